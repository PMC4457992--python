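"""Shared helpers for the test suite (independent of the code they check
wherever they serve as oracles)."""

import numpy as np

from tilling._seq import decode, encode, revcomp_str
from tilling.pele import ReadPair
from tilling.simulate import ADAPTER

_NEXT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def other_base(b: str, step: int = 1) -> str:
    for _ in range(step):
        b = _NEXT[b]
    return b


def random_seq(rng, n: int) -> str:
    return decode(rng.integers(0, 4, n).astype(np.uint8))


def pair_from_fragment(fragment: str, read_len: int = 250, q: int = 38,
                       read_id: str = "pair") -> ReadPair:
    """Error-free fully-overlapping read pair for a fragment, with adapter
    read-through when the fragment is shorter than the read."""
    pad = (ADAPTER * (read_len // len(ADAPTER) + 1))
    r1 = (fragment + pad)[:read_len]
    r2 = (revcomp_str(fragment) + pad)[:read_len]
    quals = np.full(read_len, q, dtype=np.int16)
    return ReadPair(read_id, r1, r2, quals.copy(), quals.copy())


def with_mismatches(seq: str, positions, step: int = 1) -> str:
    s = list(seq)
    for p in positions:
        s[p] = other_base(s[p], step)
    return "".join(s)


def brute_force_nonsense(amplicon):
    """Independent oracle: mutate every exonic base to every alternative,
    re-translate the complete codons with Biopython, and report the
    substitutions that introduce a new stop (amplicon-strand coordinates)."""
    from Bio.Seq import Seq

    from tilling._seq import complement_base

    start, end = amplicon.exon_interval
    exon = amplicon.sequence[start:end]
    coding = revcomp_str(exon) if amplicon.cds_strand == "-" else exon
    lead = (3 - amplicon.frame_offset) % 3
    usable = len(coding) - lead - (len(coding) - lead) % 3
    if usable <= 0:
        return set()
    ref_prot = str(Seq(coding[lead:lead + usable]).translate())
    hits = set()
    for k in range(lead, lead + usable):
        for alt in "ACGT":
            if alt == coding[k]:
                continue
            mutated = coding[:k] + alt + coding[k + 1:]
            prot = str(Seq(mutated[lead:lead + usable]).translate())
            ci = (k - lead) // 3
            if prot[ci] == "*" and ref_prot[ci] != "*":
                if amplicon.cds_strand == "-":
                    hits.add((end - 1 - k, complement_base(alt)))
                else:
                    hits.add((start + k, alt))
    return hits


def random_annotated_amplicon(rng, max_len: int = 300):
    """Random amplicon with exon, frame, strand and canonical splice
    dinucleotides, for oracle comparisons."""
    from tilling.call import SpliceSite, TargetAmplicon

    length = int(rng.integers(40, max_len + 1))
    margin = int(rng.integers(3, 12))
    strand = "+" if rng.random() < 0.5 else "-"
    frame = int(rng.integers(0, 3))
    seq = list(random_seq(rng, length))
    exon = (margin, length - margin)
    seq[exon[0] - 2:exon[0]] = ["A", "G"]
    seq[exon[1]:exon[1] + 2] = ["G", "T"]
    sites = (SpliceSite(exon[0] - 2, exon[0], "acceptor"),
             SpliceSite(exon[1], exon[1] + 2, "donor"))
    return TargetAmplicon(f"r{rng.integers(1e6)}", "".join(seq), exon, frame,
                          strand, sites)


def naive_pileup_counts(reads, offsets, ref_len: int) -> np.ndarray:
    """Brute-force per-read per-position base tally (the pileup oracle)."""
    counts = np.zeros((4, ref_len), dtype=np.int64)
    for codes, off in zip(reads, offsets):
        for j, b in enumerate(np.asarray(codes)):
            pos = off + j
            if 0 <= pos < ref_len and b < 4:
                counts[b, pos] += 1
    return counts
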