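"""Low-level DNA encoding helpers shared across the package.

Bases are encoded as small integers (A=0, C=1, G=2, T=3, N=4) so that
read-scale operations (overlap scoring, pileup counting, error injection)
can run as vectorized numpy array ops.  Anything not in ACGTN maps to N.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

ALPHABET = "ACGTN"

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement in code space; N stays N
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_STR = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (last axis)."""
    return COMPLEMENT[codes][..., ::-1]


def revcomp_str(seq: str) -> str:
    return "".join(_COMP_STR.get(b, "N") for b in reversed(seq.upper()))


def complement_base(base: str) -> str:
    return _COMP_STR[base.upper()]


def phred_decode(qual: str, offset: int = 33) -> np.ndarray:
    """Phred+33 quality string -> integer array."""
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
    return q - offset


def phred_encode(q: np.ndarray, offset: int = 33) -> str:
    """Integer quality array -> Phred+33 string (clipped to printable range)."""
    arr = (np.clip(np.asarray(q, dtype=np.int16), 0, 93) + offset).astype(np.uint8)
    return arr.tobytes().decode("ascii")
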