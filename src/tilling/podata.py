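"""Predictor of Deleterious Alleles in Target Amplicons (PoDATA).

For a target amplicon with known exon interval, reading frame and strand,
enumerate every single-nucleotide substitution that creates a premature
stop codon or hits a canonical splice dinucleotide (GT donor / AG
acceptor), then use that catalog to flag candidate calls that are likely
loss-of-function.  Codons truncated by the amplicon or exon boundary have
unknown flanking bases and are skipped (and counted), since no behavior is
defined for them.

Only the standard genetic code is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

from ._seq import complement_base, revcomp_str
from .call import TargetAmplicon, VariantCall

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

NONSENSE = "nonsense"
SPLICE_DONOR = "splice_donor"
SPLICE_ACCEPTOR = "splice_acceptor"
MISSENSE = "missense"
SILENT = "silent"
NONCODING = "noncoding"
SPLICE = "splice"
NA = "NA"

_BASES = "ACGT"

# standard genetic code, written out rather than borrowed from an aligner
# or translation library so the enumeration can be cross-checked against an
# independent translator in the tests
_CODON_TABLE: Dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_T_ORDER = "TCAG"
for _i, (_b1, _b2, _b3) in enumerate(
        (a, b, c) for a in _T_ORDER for b in _T_ORDER for c in _T_ORDER):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[_i]


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for a standard-code codon;
    'X' when the codon contains an ambiguous base."""
    return _CODON_TABLE.get(codon.upper(), "X")


@dataclass(frozen=True)
class DeleteriousCatalog:
    """All single-base substitutions in one amplicon predicted to truncate
    the protein or break a splice site.

    ``entries`` maps (position, alt_base) on the amplicon strand to the
    consequence (nonsense / splice_donor / splice_acceptor).
    ``skipped_codon_positions`` lists exonic positions whose codon was
    truncated by the exon/amplicon boundary and could not be evaluated.
    """

    amplicon_id: str
    entries: Mapping[Tuple[int, str], str]
    skipped_codon_positions: Tuple[int, ...] = ()

    def __contains__(self, key: Tuple[int, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def consequence(self, position: int, alt_base: str) -> Optional[str]:
        return self.entries.get((position, alt_base.upper()))

    def by_consequence(self, kind: str) -> List[Tuple[int, str]]:
        return sorted(k for k, v in self.entries.items() if v == kind)


def _coding_view(amplicon: TargetAmplicon) -> Tuple[str, int]:
    """(coding-strand exon sequence, exon length).

    For a minus-strand gene the coding sequence is the reverse complement
    of the exon; coding index k maps back to amplicon position
    ``exon_end - 1 - k`` and alt bases map through the complement.
    """
    start, end = amplicon.exon_interval
    exon = amplicon.sequence[start:end].upper()
    if amplicon.cds_strand == "-":
        exon = revcomp_str(exon)
    return exon, end - start


def _coding_to_amplicon(amplicon: TargetAmplicon, k: int) -> int:
    start, end = amplicon.exon_interval
    if amplicon.cds_strand == "+":
        return start + k
    return end - 1 - k


def enumerate_deleterious(amplicon: TargetAmplicon) -> DeleteriousCatalog:
    """Catalog of stop-creating and splice-dinucleotide substitutions.

    Every exonic position in a complete codon is substituted to each of the
    three alternative bases on the coding strand; a substitution is
    recorded as nonsense when the new codon is a stop and the reference
    codon is not.  Every position of each annotated splice dinucleotide
    contributes all three substitutions with the site's kind.  Entries are
    keyed on the amplicon strand so they can be compared directly with
    variant calls.
    """
    coding, n_exon = _coding_view(amplicon)
    phase0 = amplicon.frame_offset
    entries: Dict[Tuple[int, str], str] = {}
    skipped: List[int] = []

    for k in range(n_exon):
        phase = (phase0 + k) % 3
        c0 = k - phase
        if c0 < 0 or c0 + 3 > n_exon:
            skipped.append(_coding_to_amplicon(amplicon, k))
            continue
        codon = coding[c0:c0 + 3]
        if codon in STOP_CODONS or "N" in codon:
            continue
        ref_base = coding[k]
        for alt in _BASES:
            if alt == ref_base:
                continue
            new_codon = codon[:phase] + alt + codon[phase + 1:]
            if new_codon in STOP_CODONS:
                pos = _coding_to_amplicon(amplicon, k)
                amp_alt = alt if amplicon.cds_strand == "+" else complement_base(alt)
                entries[(pos, amp_alt)] = NONSENSE

    for site in amplicon.splice_sites:
        kind = SPLICE_DONOR if site.kind == "donor" else SPLICE_ACCEPTOR
        for pos in range(site.start, site.end):
            ref_base = amplicon.sequence[pos].upper()
            for alt in _BASES:
                if alt != ref_base:
                    entries[(pos, alt)] = kind

    return DeleteriousCatalog(amplicon.amplicon_id, entries,
                              tuple(sorted(skipped)))


def classify_position(amplicon: TargetAmplicon, position: int, alt_base: str,
                      catalog: Optional[DeleteriousCatalog] = None) -> str:
    """Consequence of a single substitution at an amplicon position.

    Returns one of nonsense / splice / missense / silent / noncoding / NA
    (NA: exonic but in a codon truncated by the boundary).
    """
    if catalog is None:
        catalog = enumerate_deleterious(amplicon)
    hit = catalog.consequence(position, alt_base)
    if hit == NONSENSE:
        return NONSENSE
    if hit in (SPLICE_DONOR, SPLICE_ACCEPTOR):
        return SPLICE
    if amplicon.splice_site_at(position) is not None:
        return SPLICE  # same dinucleotide; ref==alt handled by caller
    if not amplicon.is_exonic(position):
        return NONCODING

    coding, n_exon = _coding_view(amplicon)
    start, end = amplicon.exon_interval
    if amplicon.cds_strand == "+":
        k = position - start
        coding_alt = alt_base.upper()
    else:
        k = end - 1 - position
        coding_alt = complement_base(alt_base)
    phase = (amplicon.frame_offset + k) % 3
    c0 = k - phase
    if c0 < 0 or c0 + 3 > n_exon:
        return NA
    codon = coding[c0:c0 + 3]
    new_codon = codon[:phase] + coding_alt + codon[phase + 1:]
    aa_ref = translate_codon(codon)
    aa_new = translate_codon(new_codon)
    if "X" in (aa_ref, aa_new):
        return NA
    return SILENT if aa_ref == aa_new else MISSENSE


def classify_call(call: VariantCall, catalog: DeleteriousCatalog,
                  amplicon: TargetAmplicon) -> str:
    """Set and return the consequence of a variant call."""
    if not 0 <= call.position < len(amplicon):
        raise ValueError(
            f"call position {call.position} outside amplicon {amplicon.amplicon_id}")
    call.consequence = classify_position(amplicon, call.position,
                                         call.alt_base, catalog)
    return call.consequence


# ---------------------------------------------------------------------------
# ENU substitution spectrum
# ---------------------------------------------------------------------------

SUBSTITUTIONS: Tuple[Tuple[str, str], ...] = tuple(
    (r, a) for r in _BASES for a in _BASES if r != a)

#: substitutions that change the base-pair class (A:T <-> G:C), ~75% of the
#: ENU spectrum; the remaining quarter maintains pairing (A<->T, G<->C)
PAIRING_ALTERING: FrozenSet[Tuple[str, str]] = frozenset(
    (r, a) for r, a in SUBSTITUTIONS if (r in "AT") != (a in "AT"))


def enu_spectrum_weights(
        weights: Optional[Mapping[Tuple[str, str], float]] = None,
        pairing_altering_mass: float = 0.75) -> Dict[Tuple[str, str], float]:
    """Normalized probabilities over the 12 ordered substitutions.

    With no explicit weights, ``pairing_altering_mass`` (default 0.75, the
    ENU pairing-altering share) is spread uniformly over the 8 substitutions
    that flip A:T <-> G:C pairing and the remainder over the 4 that keep it.
    Explicit weights (missing entries count as 0) are simply normalized.
    """
    if weights is None:
        w = {s: (pairing_altering_mass / 8 if s in PAIRING_ALTERING
                 else (1 - pairing_altering_mass) / 4)
             for s in SUBSTITUTIONS}
    else:
        w = {s: float(weights.get(s, 0.0)) for s in SUBSTITUTIONS}
    if any(v < 0 for v in w.values()):
        raise ValueError("substitution weights must be non-negative")
    total = sum(w.values())
    if total <= 0:
        raise ValueError("substitution weights must not all be zero")
    return {s: v / total for s, v in w.items()}
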