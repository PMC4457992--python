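"""Readers and writers for the pipeline's file formats.

FASTQ (Phred+33, optionally gzipped), reference FASTA, the per-amplicon
annotation TSV, call tables (TSV) and a minimal single-sample VCF view.

Coordinate conventions: everything on disk is 1-based inclusive
(annotation intervals, call positions, VCF POS); everything in memory is
0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import encode, phred_decode, phred_encode
from .call import SpliceSite, TargetAmplicon, VariantCall


class FormatError(ValueError):
    """A malformed input file (message names the file and record)."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) records from a FASTQ file."""
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: record {i + 1}: {exc}") from exc
            title, seq, qual = rec
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record {i + 1}: sequence and quality lengths differ")
            yield title.split()[0], seq, qual
            i += 1


def write_fastq(path, records: Iterable[Tuple[str, str, str]]) -> int:
    """Write (id, seq, qual-string) records; returns the record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq_arrays(path) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Load an equal-length FASTQ file into code/quality matrices.

    Returns (ids, S, Q) with S a (n, L) uint8 base-code matrix; raises
    FormatError when read lengths differ (amplicon reads are fixed-length).
    """
    ids: List[str] = []
    seqs: List[np.ndarray] = []
    quals: List[np.ndarray] = []
    L = None
    for i, (rid, seq, qual) in enumerate(read_fastq(path)):
        if L is None:
            L = len(seq)
        elif len(seq) != L:
            raise FormatError(
                f"{path}: record {i + 1}: read length {len(seq)} != {L}")
        ids.append(rid)
        seqs.append(encode(seq))
        quals.append(phred_decode(qual))
    if not ids:
        return [], np.empty((0, 0), dtype=np.uint8), np.empty((0, 0), dtype=np.int16)
    return ids, np.stack(seqs), np.stack(quals)


def write_fastq_arrays(path, ids: Sequence[str], S: np.ndarray, Q: np.ndarray) -> int:
    from ._seq import decode

    return write_fastq(path, ((rid, decode(s), phred_encode(q))
                              for rid, s, q in zip(ids, S, Q)))


# ---------------------------------------------------------------------------
# references and annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["amplicon_id", "exon_start", "exon_end", "frame_offset",
                      "cds_strand", "donor_pos", "acceptor_pos"]


def read_fasta(path) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, seqs: Dict[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _parse_positions(val) -> List[int]:
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return []
    s = str(val).strip()
    if not s or s.lower() in ("na", "nan", "."):
        return []
    return [int(x) for x in s.split(",")]


def read_annotation(annot_path, fasta_path) -> List[TargetAmplicon]:
    """Combine the reference FASTA with its annotation TSV.

    The TSV columns are ``amplicon_id, exon_start, exon_end, frame_offset,
    cds_strand, donor_pos, acceptor_pos`` with 1-based inclusive exon
    coordinates and 1-based positions of the first base of each splice
    dinucleotide (comma-separated lists; empty/NA for none).
    """
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(annot_path, sep="\t",
                     dtype={"amplicon_id": str, "cds_strand": str,
                            "donor_pos": str, "acceptor_pos": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{annot_path}: missing columns {sorted(missing)}")
    amplicons = []
    for _, row in df.iterrows():
        aid = row["amplicon_id"]
        if aid not in seqs:
            raise FormatError(f"{annot_path}: amplicon {aid!r} not in FASTA")
        sites = []
        for pos in _parse_positions(row["donor_pos"]):
            sites.append(SpliceSite(pos - 1, pos + 1, "donor"))
        for pos in _parse_positions(row["acceptor_pos"]):
            sites.append(SpliceSite(pos - 1, pos + 1, "acceptor"))
        amplicons.append(TargetAmplicon(
            aid, seqs[aid],
            (int(row["exon_start"]) - 1, int(row["exon_end"])),
            int(row["frame_offset"]), str(row["cds_strand"]), tuple(sites)))
    return amplicons


def write_annotation(path, amplicons: Sequence[TargetAmplicon]) -> None:
    rows = []
    for a in amplicons:
        donors = ",".join(str(s.start + 1) for s in a.splice_sites if s.kind == "donor")
        acceptors = ",".join(str(s.start + 1) for s in a.splice_sites
                             if s.kind == "acceptor")
        rows.append({
            "amplicon_id": a.amplicon_id,
            "exon_start": a.exon_interval[0] + 1,
            "exon_end": a.exon_interval[1],
            "frame_offset": a.frame_offset,
            "cds_strand": a.cds_strand,
            "donor_pos": donors,
            "acceptor_pos": acceptors,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# call tables
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["amplicon_id", "pos_1based", "ref", "alt", "pool_id",
                "variant_reads", "total_reads", "frequency", "consequence",
                "filter_status"]


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [{
        "amplicon_id": c.amplicon_id,
        "pos_1based": c.position_1based,
        "ref": c.ref_base,
        "alt": c.alt_base,
        "pool_id": c.pool_id,
        "variant_reads": c.variant_reads,
        "total_reads": c.total_reads,
        "frequency": c.frequency,
        "consequence": c.consequence,
        "filter_status": c.filter_status if c.filter_status is not None else "NA",
    } for c in calls]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(path, calls: Sequence[VariantCall]) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path) -> List[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str, "pool_id": str})
    out = []
    for _, row in df.iterrows():
        status = row["filter_status"]
        out.append(VariantCall(
            row["amplicon_id"], int(row["pos_1based"]) - 1, row["ref"],
            row["alt"], str(row["pool_id"]), int(row["variant_reads"]),
            int(row["total_reads"]), float(row["frequency"]),
            str(row["consequence"]),
            None if (pd.isna(status) or status == "NA") else str(status)))
    return out


# ---------------------------------------------------------------------------
# VCF (convenience view: one sample per pool)
# ---------------------------------------------------------------------------

def write_vcf(path, calls: Sequence[VariantCall],
              amplicons: Sequence[TargetAmplicon], sample: str = "POOL") -> int:
    """Write calls as a minimal VCF 4.2 with AD/DP/AF-style fields.

    Amplicons act as contigs; one call per data line.  Returns the number
    of data lines written.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Variant read frequency F">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total reads at site">',
        '##FILTER=<ID=polymorphism,Description="F above the polymorphism ceiling">',
        '##FILTER=<ID=pcr_noise,Description="F below the PCR-noise floor">',
        '##FILTER=<ID=low_coverage,Description="Position below the coverage floor">',
    ]
    for a in amplicons:
        lines.append(f"##contig=<ID={a.amplicon_id},length={len(a)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    n = 0
    for c in calls:
        filt = "PASS" if c.filter_status in (None, "pass") else c.filter_status
        ref_depth = c.total_reads - c.variant_reads
        lines.append("\t".join([
            c.amplicon_id, str(c.position_1based), ".", c.ref_base, c.alt_base,
            ".", filt, f"AF={c.frequency:.6g}", "AD:DP",
            f"{ref_depth},{c.variant_reads}:{c.total_reads}"]))
        n += 1
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")
    return n
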