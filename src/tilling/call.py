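"""Read assignment, pileup construction and variant-frequency calling.

Merged consensus reads are assigned to their reference amplicon by an
exhaustive ungapped scan (amplicons are short, known sequences and the
mutagen induces substitutions only, so gapped alignment buys nothing and
indel-bearing reads are deliberately dropped).  Per-pool pileups count the
four bases at every reference position, one count per original read pair,
and every non-reference base observed at a position becomes a raw call
with frequency

    F = variant reads / total reads at that position in that pool.

Frequency-window and coverage filtering is the screen module's job; this
module reports every observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import ALPHABET, N, decode, encode

_BASES = "ACGT"


@dataclass(frozen=True)
class SpliceSite:
    """A canonical splice dinucleotide inside an amplicon (0-based,
    half-open interval of length 2, outside the exon)."""
    start: int
    end: int
    kind: str  # "donor" or "acceptor"

    def __post_init__(self) -> None:
        if self.end - self.start != 2:
            raise ValueError("splice site must be a 2 bp dinucleotide")
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"unknown splice site kind {self.kind!r}")


@dataclass(frozen=True)
class TargetAmplicon:
    """A reference amplicon with its exon structure.

    ``sequence`` is the plus strand of the amplicon as sequenced;
    ``exon_interval`` is 0-based half-open within the amplicon;
    ``frame_offset`` (0-2) is the phase of the first exonic base in its
    codon, counted along the coding strand; ``cds_strand`` gives the coding
    strand relative to the amplicon.  Splice dinucleotides flank the exon:
    a donor starts at ``exon_end``, an acceptor ends at ``exon_start``.
    """

    amplicon_id: str
    sequence: str
    exon_interval: Tuple[int, int]
    frame_offset: int = 0
    cds_strand: str = "+"
    splice_sites: Tuple[SpliceSite, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "splice_sites",
                           tuple(sorted(self.splice_sites,
                                        key=lambda s: (s.start, s.kind))))
        start, end = self.exon_interval
        L = len(self.sequence)
        if not (0 <= start <= end <= L):
            raise ValueError(
                f"{self.amplicon_id}: exon interval {self.exon_interval} "
                f"outside amplicon of length {L}")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.amplicon_id}: frame_offset must be 0-2")
        if self.cds_strand not in ("+", "-"):
            raise ValueError(f"{self.amplicon_id}: cds_strand must be '+' or '-'")
        for s in self.splice_sites:
            if not (0 <= s.start and s.end <= L):
                raise ValueError(f"{self.amplicon_id}: splice site {s} outside amplicon")
            if s.start < end and s.end > start:
                raise ValueError(f"{self.amplicon_id}: splice site {s} overlaps the exon")
            if s.kind == "donor" and s.start != end:
                raise ValueError(
                    f"{self.amplicon_id}: donor dinucleotide must start at the exon end")
            if s.kind == "acceptor" and s.end != start:
                raise ValueError(
                    f"{self.amplicon_id}: acceptor dinucleotide must end at the exon start")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def is_exonic(self, pos: int) -> bool:
        return self.exon_interval[0] <= pos < self.exon_interval[1]

    def splice_site_at(self, pos: int) -> Optional[SpliceSite]:
        for s in self.splice_sites:
            if s.start <= pos < s.end:
                return s
        return None


@dataclass(frozen=True)
class Assignment:
    amplicon_id: str
    offset: int          # read position 0 sits at this reference coordinate
    mismatches: int
    aligned: int         # non-N read bases on the reference


@dataclass
class PoolPileup:
    """Per-position counts of the four bases for one amplicon in one pool."""

    amplicon_id: str
    pool_id: str
    counts: np.ndarray  # (4, L) int64, rows A, C, G, T

    @classmethod
    def empty(cls, amplicon: TargetAmplicon, pool_id: str) -> "PoolPileup":
        return cls(amplicon.amplicon_id, str(pool_id),
                   np.zeros((4, len(amplicon)), dtype=np.int64))

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def add_read(self, codes: np.ndarray, offset: int) -> None:
        """Count one read's bases (N bases contribute nothing)."""
        L = self.counts.shape[1]
        j0 = max(0, -offset)
        j1 = min(codes.size, L - offset)
        if j0 >= j1:
            return
        window = codes[j0:j1]
        pos = np.arange(j0 + offset, j1 + offset)
        keep = window != N
        # a read covers each reference position at most once, so plain
        # fancy-index increment is safe
        self.counts[window[keep], pos[keep]] += 1

    def add_reads(self, reads: Iterable[np.ndarray], offsets: Iterable[int]) -> None:
        for codes, off in zip(reads, offsets):
            self.add_read(codes, off)


@dataclass
class VariantCall:
    amplicon_id: str
    position: int        # 0-based within the amplicon
    ref_base: str
    alt_base: str
    pool_id: str
    variant_reads: int
    total_reads: int
    frequency: float
    consequence: str = "NA"
    filter_status: Optional[str] = None

    @property
    def position_1based(self) -> int:
        return self.position + 1


def _check_refs(refs: Sequence[TargetAmplicon]) -> None:
    if not refs:
        raise ValueError("no reference amplicons given")
    ids = [r.amplicon_id for r in refs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate amplicon ids in reference set")


def assign_reads(reads: Sequence[np.ndarray], refs: Sequence[TargetAmplicon],
                 max_mismatch_frac: float = 0.10,
                 min_aligned_frac: float = 0.80) -> List[Optional[Assignment]]:
    """Assign each read (code array) to its best-matching amplicon.

    Every reference is scanned at every ungapped offset placing at least
    ``min_aligned_frac`` of the read on the reference.  The unique
    (amplicon, offset) with the fewest mismatches wins if its mismatch
    fraction over aligned non-N bases is <= ``max_mismatch_frac``; a tie
    for fewest mismatches between two placements is ambiguous and the read
    is left unassigned (``None``), as is any read matching nothing well
    (e.g. one carrying an indel).
    """
    _check_refs(refs)
    n = len(reads)
    best_mm = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
    best_aligned = np.zeros(n, dtype=np.int32)
    best_key: List[Optional[Tuple[str, int]]] = [None] * n
    tied = np.zeros(n, dtype=bool)

    # group reads of equal length so the offset scan vectorizes
    lengths = np.array([r.size for r in reads], dtype=np.int64)
    for L in np.unique(lengths):
        if L == 0:
            continue
        rows = np.flatnonzero(lengths == L)
        R = np.stack([reads[i] for i in rows]).astype(np.uint8)
        min_aligned = int(np.ceil(min_aligned_frac * L))
        read_n = R == N
        for ref in refs:
            rc = ref.codes
            M = rc.size
            for d in range(min_aligned - L, M - min_aligned + 1):
                j0 = max(0, -d)
                j1 = min(L, M - d)
                if j1 - j0 < min_aligned:
                    continue
                x = R[:, j0:j1]
                y = rc[j0 + d:j1 + d]
                valid = ~read_n[:, j0:j1] & (y != N)
                mm = np.count_nonzero((x != y) & valid, axis=1).astype(np.int32)
                al = np.count_nonzero(valid, axis=1).astype(np.int32)
                cur = best_mm[rows]
                better = mm < cur
                equal = mm == cur
                tied[rows[equal]] = True
                upd = rows[better]
                best_mm[upd] = mm[better]
                best_aligned[upd] = al[better]
                tied[upd] = False
                for r in upd:
                    best_key[r] = (ref.amplicon_id, d)

    out: List[Optional[Assignment]] = [None] * n
    for i in range(n):
        if best_key[i] is None or tied[i] or best_aligned[i] == 0:
            continue
        if best_mm[i] / best_aligned[i] <= max_mismatch_frac:
            amp, d = best_key[i]
            out[i] = Assignment(amp, d, int(best_mm[i]), int(best_aligned[i]))
    return out


def assign_read(read, refs: Sequence[TargetAmplicon],
                max_mismatch_frac: float = 0.10,
                min_aligned_frac: float = 0.80) -> Optional[Assignment]:
    """Single-read convenience wrapper around :func:`assign_reads`;
    accepts a string or a code array."""
    codes = encode(read) if isinstance(read, str) else np.asarray(read, dtype=np.uint8)
    return assign_reads([codes], refs, max_mismatch_frac, min_aligned_frac)[0]


def build_pileup(reads: Sequence[np.ndarray],
                 assignments: Sequence[Optional[Assignment]],
                 amplicon: TargetAmplicon, pool_id: str) -> PoolPileup:
    """Pileup of all reads assigned to one amplicon in one pool.

    Each merged consensus read contributes one count per covered position
    (never one per mate - that is the substance of the error suppression).
    Reads assigned elsewhere or unassigned are skipped.
    """
    pp = PoolPileup.empty(amplicon, pool_id)
    L = len(amplicon)
    for codes, asg in zip(reads, assignments):
        if asg is None or asg.amplicon_id != amplicon.amplicon_id:
            continue
        if asg.offset >= L or asg.offset + codes.size <= 0:
            raise ValueError(
                f"assignment offset {asg.offset} outside amplicon "
                f"{amplicon.amplicon_id}")
        pp.add_read(codes, asg.offset)
    return pp


def call_variants(pileup: PoolPileup, amplicon: TargetAmplicon,
                  min_alt_reads: int = 1) -> List[VariantCall]:
    """One raw call per (position, non-reference base) with enough reads.

    F is the variant read count over the total depth at that position;
    positions with zero depth yield no calls.  Consequence annotation and
    filtering are applied downstream.
    """
    if pileup.counts.shape[1] != len(amplicon):
        raise ValueError("pileup length does not match amplicon")
    ref_codes = amplicon.codes
    depth = pileup.depth
    calls: List[VariantCall] = []
    for alt_code in range(4):
        pos_hits = np.flatnonzero(
            (pileup.counts[alt_code] >= min_alt_reads)
            & (ref_codes != alt_code) & (depth > 0))
        for pos in pos_hits:
            vr = int(pileup.counts[alt_code, pos])
            tr = int(depth[pos])
            ref_b = amplicon.sequence[pos].upper()
            calls.append(VariantCall(
                amplicon.amplicon_id, int(pos), ref_b, _BASES[alt_code],
                pileup.pool_id, vr, tr, vr / tr))
    calls.sort(key=lambda c: (c.position, c.alt_base))
    return calls
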