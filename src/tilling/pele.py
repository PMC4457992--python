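"""Paired-End Low-Error (PELE) merging of fully-overlapping read pairs.

An amplicon shorter than twice the read length yields a read pair whose two
mates cover the same molecule from opposite ends.  After reverse-
complementing the second mate, the pair is scanned over every relative
offset; the offset with the most matching bases defines the overlap.  A
sequencing error arises independently in each mate, so a true base is read
identically twice while an error almost never is: pairs whose overlap
identity falls below ``min_identity`` (default 0.97) are rejected outright,
which removes the large majority of sequencing error from downstream
variant calling.

Offset convention: position ``j`` of the reverse-complemented second mate
pairs with position ``offset + j`` of the first mate.  ``offset == 0`` is a
perfectly overlapping pair; a *negative* offset means the sequenced
fragment was shorter than the read and each mate read through into adapter,
which is trimmed; a *positive* offset means the fragment was longer than
the read and the non-overlapping flanks are genuine fragment sequence,
which is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np

from ._seq import N, decode, encode, phred_decode, revcomp

MERGED = "merged"
REJECTED_IDENTITY = "rejected_identity"
REJECTED_NO_OVERLAP = "rejected_no_overlap"

# quality assigned to a consensus N produced by a quality tie at a mismatch
_TIE_QUAL = 2
_MAX_QUAL = 99


@dataclass(frozen=True)
class MergeConfig:
    """Tunables of the PELE merge.

    min_identity:
        Minimum fraction of matching bases over the overlap for a pair to be
        accepted (0.97: up to 3% mismatches tolerated).
    min_overlap:
        Smallest overlap length considered a real overlap; precludes
        spurious short alignments.
    max_offset_search:
        Bound on |offset| scanned; ``None`` scans every offset compatible
        with ``min_overlap``.
    min_anchor_identity:
        Plausibility floor: if even the best-scoring offset matches fewer
        than this fraction of overlapped bases, the pair is treated as
        having no overlap at all (two unrelated reads score ~0.25).
    n_policy:
        How N bases inside the overlap count in identity: ``"count_against"``
        (default; an N can never support a match) or ``"exclude"`` (N
        positions are dropped from the denominator).
    """

    min_identity: float = 0.97
    min_overlap: int = 50
    max_offset_search: Optional[int] = None
    min_anchor_identity: float = 0.5
    n_policy: Literal["count_against", "exclude"] = "count_against"

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.n_policy not in ("count_against", "exclude"):
            raise ValueError(f"unknown n_policy {self.n_policy!r}")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ")

    @classmethod
    def from_strings(cls, read_id: str, seq1: str, qual1: str,
                     seq2: str, qual2: str) -> "ReadPair":
        return cls(read_id, seq1, seq2, phred_decode(qual1), phred_decode(qual2))


@dataclass(frozen=True)
class Overlap:
    offset: int
    length: int
    matches: int
    mismatches: int
    n_positions: int
    identity: float


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: np.ndarray
    status: str
    offset: int = 0
    overlap_len: int = 0
    mismatches: int = 0
    n_positions: int = 0
    identity: float = 0.0

    @property
    def merged(self) -> bool:
        return self.status == MERGED


def _identity(matches: int, length: int, n_positions: int, cfg: MergeConfig) -> float:
    if cfg.n_policy == "exclude":
        denom = length - n_positions
    else:
        denom = length
    return matches / denom if denom > 0 else 0.0


def _offset_range(len1: int, len2: int, cfg: MergeConfig) -> range:
    lo = -(len2 - cfg.min_overlap)
    hi = len1 - cfg.min_overlap
    if cfg.max_offset_search is not None:
        lo = max(lo, -cfg.max_offset_search)
        hi = min(hi, cfg.max_offset_search)
    return range(lo, hi + 1)


def find_overlap(pair: ReadPair, cfg: MergeConfig = MergeConfig()) -> Optional[Overlap]:
    """Best ungapped overlap between mate 1 and the reverse complement of
    mate 2, or ``None`` when no plausible overlap exists.

    Scans every offset with overlap >= ``min_overlap`` and keeps the offset
    with the most matching bases (ties broken toward the longer overlap,
    then the smaller offset).  Returns ``None`` if no offset is feasible or
    the best offset's identity is below ``min_anchor_identity``.
    """
    s1 = encode(pair.seq1)
    s2 = revcomp(encode(pair.seq2))
    if s1.size == 0 or s2.size == 0:
        return None
    best = None  # (matches, length, offset, mismatches, n_positions)
    for d in _offset_range(s1.size, s2.size, cfg):
        a1 = max(0, d)
        b1 = min(s1.size, d + s2.size)
        w = b1 - a1
        if w < cfg.min_overlap:
            continue
        x = s1[a1:b1]
        y = s2[a1 - d:b1 - d]
        valid = (x != N) & (y != N)
        matches = int(np.count_nonzero((x == y) & valid))
        if best is None or matches > best[0] or (matches == best[0] and w > best[1]):
            mism = int(np.count_nonzero((x != y) & valid))
            npos = w - matches - mism
            best = (matches, w, d, mism, npos)
    if best is None:
        return None
    matches, w, d, mism, npos = best
    ident = _identity(matches, w, npos, cfg)
    if ident < cfg.min_anchor_identity:
        return None
    return Overlap(d, w, matches, mism, npos, ident)


def _consensus(s1, q1, s2, q2):
    """Per-position consensus of two aligned code/quality arrays."""
    out = s1.copy()
    q = np.minimum(q1.astype(np.int64) + q2, _MAX_QUAL)
    n1 = s1 == N
    n2 = s2 == N
    # one-sided N: the called base wins with its own quality
    only2 = n1 & ~n2
    out[only2] = s2[only2]
    q[n1 | n2] = np.where(n1, q2, q1)[n1 | n2]
    q[n1 & n2] = _TIE_QUAL
    # true disagreements: higher quality wins with quality |q1-q2|; tie -> N
    dis = (s1 != s2) & ~n1 & ~n2
    win2 = dis & (q2 > q1)
    out[win2] = s2[win2]
    q[dis] = np.abs(q1 - q2)[dis]
    tie = dis & (q1 == q2)
    out[tie] = N
    q[tie] = _TIE_QUAL
    return out, q


def merge_pair(pair: ReadPair, cfg: MergeConfig = MergeConfig()) -> MergedRead:
    """Merge one read pair into a consensus read, or reject it.

    Accepted pairs get a consensus covering the inferred fragment: at
    agreeing positions the base is kept with quality ``min(99, q1+q2)``; at
    disagreeing positions the higher-quality base is kept with quality
    ``|q1-q2|`` (a quality tie yields N).  Adapter read-through (negative
    offset) is trimmed; fragment flanks (positive offset) are kept.
    """
    ov = find_overlap(pair, cfg)
    if ov is None:
        return MergedRead(pair.read_id, "", np.empty(0, dtype=np.int16),
                          REJECTED_NO_OVERLAP)
    if ov.identity < cfg.min_identity:
        return MergedRead(pair.read_id, "", np.empty(0, dtype=np.int16),
                          REJECTED_IDENTITY, ov.offset, ov.length,
                          ov.mismatches, ov.n_positions, ov.identity)
    s1 = encode(pair.seq1)
    q1 = np.asarray(pair.qual1, dtype=np.int16)
    s2 = revcomp(encode(pair.seq2))
    q2 = np.asarray(pair.qual2, dtype=np.int16)[::-1]
    seq, qual = _merged_arrays(s1, q1, s2, q2, ov.offset)
    return MergedRead(pair.read_id, decode(seq), qual, MERGED, ov.offset,
                      ov.length, ov.mismatches, ov.n_positions, ov.identity)


def _merged_arrays(s1, q1, s2, q2, d):
    """Consensus sequence/quality arrays for a pair aligned at offset d
    (s2 already reverse-complemented, q2 already reversed)."""
    a1 = max(0, d)
    b1 = min(s1.size, d + s2.size)
    cons, cq = _consensus(s1[a1:b1], q1[a1:b1], s2[a1 - d:b1 - d], q2[a1 - d:b1 - d])
    if d < 0:
        # fragment shorter than the reads: everything outside the overlap
        # is adapter read-through on both mates
        return cons, cq
    parts = [s1[:a1], cons]
    qparts = [q1[:a1], cq]
    if d + s2.size > s1.size:
        parts.append(s2[b1 - d:])
        qparts.append(q2[b1 - d:])
    elif b1 < s1.size:
        parts.append(s1[b1:])
        qparts.append(q1[b1:])
    return np.concatenate(parts), np.concatenate(qparts)


def expected_discard_fraction(read_err: float, overlap_len: int,
                              cfg: MergeConfig = MergeConfig()) -> float:
    """Closed-form probability that an error-free-template pair is rejected.

    With per-base per-mate error probability ``e`` (independent mates,
    uniform substitution), a given overlap position disagrees with
    probability ``p = 2e(1-e) + (2/3)e^2`` (both mates hitting the same
    wrong base still agree).  The pair is rejected when the number of
    disagreements exceeds ``floor((1-min_identity) * overlap_len)``, so the
    discard probability is the corresponding binomial tail.
    """
    from scipy.stats import binom

    if not 0 <= read_err < 1:
        raise ValueError("read_err must be in [0, 1)")
    if read_err == 0:
        return 0.0
    p_mm = 2 * read_err * (1 - read_err) + (2.0 / 3.0) * read_err ** 2
    k_max = int(np.floor((1 - cfg.min_identity) * overlap_len))
    return float(binom.sf(k_max, overlap_len, p_mm))


# ---------------------------------------------------------------------------
# batch path: same algorithm, vectorized over equal-length pairs
# ---------------------------------------------------------------------------

@dataclass
class MergeBatch:
    """Vectorized merge result for a batch of equal-length read pairs.

    ``seqs``/``quals`` hold one consensus code/quality array per pair
    (``None`` for rejected pairs).  Scalar metadata lives in parallel numpy
    arrays; ``status`` uses the same strings as :class:`MergedRead`.
    """

    status: np.ndarray
    offset: np.ndarray
    overlap_len: np.ndarray
    mismatches: np.ndarray
    n_positions: np.ndarray
    identity: np.ndarray
    seqs: list
    quals: list

    @property
    def n_pairs(self) -> int:
        return self.status.size

    @property
    def n_merged(self) -> int:
        return int(np.count_nonzero(self.status == MERGED))

    def counts(self) -> dict:
        return {
            "pairs_in": self.n_pairs,
            "merged": self.n_merged,
            "rejected_identity": int(np.count_nonzero(self.status == REJECTED_IDENTITY)),
            "rejected_no_overlap": int(np.count_nonzero(self.status == REJECTED_NO_OVERLAP)),
        }

    @property
    def discard_fraction(self) -> float:
        return 1.0 - self.n_merged / self.n_pairs if self.n_pairs else 0.0


def merge_pairs(S1: np.ndarray, Q1: np.ndarray, S2: np.ndarray, Q2: np.ndarray,
                cfg: MergeConfig = MergeConfig()) -> MergeBatch:
    """Merge a batch of read pairs given as code/quality matrices.

    ``S1``/``S2`` are (n, L1)/(n, L2) uint8 code matrices as produced by
    :func:`tilling._seq.encode` (mate 2 in sequencing orientation; the
    reverse complement is taken here), ``Q1``/``Q2`` the matching integer
    quality matrices.  Equivalent to calling :func:`merge_pair` on each
    pair; the offset scan is vectorized across the batch.
    """
    S1 = np.ascontiguousarray(S1, dtype=np.uint8)
    Q1 = np.asarray(Q1, dtype=np.int16)
    S2r = np.ascontiguousarray(revcomp(np.asarray(S2, dtype=np.uint8)))
    Q2r = np.asarray(Q2, dtype=np.int16)[:, ::-1]
    n, L1 = S1.shape
    L2 = S2r.shape[1]

    best_m = np.full(n, -1, dtype=np.int32)
    best_w = np.zeros(n, dtype=np.int32)
    best_d = np.zeros(n, dtype=np.int32)
    for d in _offset_range(L1, L2, cfg):
        a1 = max(0, d)
        b1 = min(L1, d + L2)
        w = b1 - a1
        if w < cfg.min_overlap:
            continue
        x = S1[:, a1:b1]
        y = S2r[:, a1 - d:b1 - d]
        m = np.count_nonzero((x == y) & (x != N) & (y != N), axis=1).astype(np.int32)
        upd = (m > best_m) | ((m == best_m) & (w > best_w))
        best_m[upd] = m[upd]
        best_w[upd] = w
        best_d[upd] = d

    status = np.full(n, REJECTED_NO_OVERLAP, dtype=object)
    offset = best_d.copy()
    overlap = best_w.copy()
    mism = np.zeros(n, dtype=np.int32)
    npos = np.zeros(n, dtype=np.int32)
    ident = np.zeros(n)
    seqs: list = [None] * n
    quals: list = [None] * n

    feasible = best_m >= 0
    for d in np.unique(best_d[feasible]):
        rows = np.flatnonzero(feasible & (best_d == d))
        a1 = max(0, int(d))
        b1 = min(L1, int(d) + L2)
        w = b1 - a1
        x = S1[rows, a1:b1]
        y = S2r[rows, a1 - d:b1 - d]
        valid = (x != N) & (y != N)
        g_m = np.count_nonzero((x == y) & valid, axis=1)
        g_mm = np.count_nonzero((x != y) & valid, axis=1)
        g_np = w - g_m - g_mm
        if cfg.n_policy == "exclude":
            denom = np.maximum(w - g_np, 1).astype(float)
            g_id = np.where(w - g_np > 0, g_m / denom, 0.0)
        else:
            g_id = g_m / w
        mism[rows] = g_mm
        npos[rows] = g_np
        ident[rows] = g_id
        anchored = g_id >= cfg.min_anchor_identity
        ok = g_id >= cfg.min_identity
        status[rows[anchored & ~ok]] = REJECTED_IDENTITY
        status[rows[anchored & ok]] = MERGED
        for r in rows[anchored & ok]:
            seq, qual = _merged_arrays(S1[r], Q1[r], S2r[r], Q2r[r], int(d))
            seqs[r] = seq
            quals[r] = qual
    # pairs that never anchored keep offset/overlap 0 in the report
    no_ov = status == REJECTED_NO_OVERLAP
    offset[no_ov] = 0
    overlap[no_ov] = 0
    mism[no_ov] = 0
    npos[no_ov] = 0
    ident[no_ov] = 0.0
    return MergeBatch(status, offset, overlap, mism, npos, ident, seqs, quals)
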