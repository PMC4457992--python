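"""Synthetic ENU-library read simulator.

Emulates the full wet-lab path that produces the pipeline's input: a
library of diploid individuals each carrying unique heterozygous induced
mutations (plus shared founder polymorphisms), pooled; per-pool PCR of
short amplicons with a two-tier error model (early-cycle "jackpot"
lineages whose errors recur across reads at frequency ~2^(1-c), plus
independent late-cycle per-read errors); and fully-overlapping paired-end
reads with independent per-base sequencing errors on each mate.

Defaults reflect the study conditions: 2 x 250 bp reads of 210-270 bp
amplicons, 288-fish sequencing pools, 30 PCR cycles, ~1% per-base
sequencing error, and a nominal per-pool depth of 10,854 read pairs (the
reported mean per-pool coverage).  All randomness flows from a single
seeded generator in a fixed draw order, so identical configurations
produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._seq import COMPLEMENT, decode, encode
from .call import SpliceSite, TargetAmplicon
from .podata import SUBSTITUTIONS, enu_spectrum_weights
from .pool_design import DeconvolutionPlan, LibraryDesign, build_pools

_BASES = "ACGT"

#: read-through adapter appended when the fragment is shorter than the read
#: (Nextera transposase sequence); tiled if more padding is needed
ADAPTER = "CTGTCTCTTATACACATCTCCGAGCCCACGAGACATCTCGTATGCCGTCTTCTGCTTG"

PLANTED = "planted"
ENU = "enu"
POLYMORPHISM = "polymorphism"


@dataclass(frozen=True)
class AmplificationDispersion:
    """Lognormal spread of realized depth (median-preserving).

    Defaults give ~10-fold 95% range across fragments and ~3-fold across
    pools, matching the observed depth variability; set to zero (or pass
    ``dispersion=None``) for deterministic depth.
    """

    fragment_sigma: float = math.log(10) / 4
    pool_sigma: float = math.log(3) / 4
    fish_sigma: float = 0.0


@dataclass(frozen=True)
class PlantedVariant:
    amplicon_id: str
    position: int
    alt: str
    fish_id: int


@dataclass(frozen=True)
class Polymorphism:
    amplicon_id: str
    position: int
    alt: str
    frequency: float  # population allele frequency (> the screen's f_max)


@dataclass(frozen=True)
class SimConfig:
    seed: int
    design: LibraryDesign
    amplicons: Tuple[TargetAmplicon, ...]
    planted_variants: Tuple[PlantedVariant, ...] = ()
    polymorphisms: Tuple[Polymorphism, ...] = ()
    enu_rate: float = 0.0          # expected het mutations / fish / amplicon
    pcr_cycles: int = 30
    pcr_error_rate: float = 1e-6   # per base per cycle
    seq_error_rate: float = 0.01   # per base per mate
    read_len: int = 250
    depth_per_pool: int = 10854    # read pairs per amplicon per pool
    dispersion: Optional[AmplificationDispersion] = AmplificationDispersion()
    q_high: int = 38
    q_low: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        object.__setattr__(self, "planted_variants", tuple(self.planted_variants))
        object.__setattr__(self, "polymorphisms", tuple(self.polymorphisms))
        for name in ("enu_rate", "pcr_error_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.read_len < 1 or self.depth_per_pool < 1 or self.pcr_cycles < 0:
            raise ValueError("read_len/depth_per_pool/pcr_cycles out of range")
        amp_ids = {a.amplicon_id: a for a in self.amplicons}
        if len(amp_ids) != len(self.amplicons):
            raise ValueError("duplicate amplicon ids")
        for pv in list(self.planted_variants) + list(self.polymorphisms):
            amp = amp_ids.get(pv.amplicon_id)
            if amp is None:
                raise ValueError(f"unknown amplicon {pv.amplicon_id!r}")
            if not 0 <= pv.position < len(amp):
                raise ValueError(
                    f"position {pv.position} outside amplicon {pv.amplicon_id}")
            if pv.alt.upper() not in _BASES:
                raise ValueError(f"alt must be one of ACGT, got {pv.alt!r}")
            if pv.alt.upper() == amp.sequence[pv.position].upper():
                raise ValueError(
                    f"alt equals reference at {pv.amplicon_id}:{pv.position}")
        for pv in self.planted_variants:
            if not 0 <= pv.fish_id < self.design.n_fish:
                raise ValueError(f"fish_id {pv.fish_id} outside library")
        for poly in self.polymorphisms:
            if not 0 < poly.frequency <= 1:
                raise ValueError("polymorphism frequency must be in (0, 1]")

    def amplicon(self, amplicon_id: str) -> TargetAmplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)


@dataclass(frozen=True)
class GenotypeVariant:
    amplicon_id: str
    position: int
    alt: str
    copies: int     # alleles of this fish carrying the variant
    kind: str       # planted / enu / polymorphism


def random_amplicon(rng: np.random.Generator, amplicon_id: str = "amp1",
                    length: int = 240, exon_margin: int = 30,
                    cds_strand: str = "+", frame_offset: int = 0,
                    with_splice_sites: bool = True) -> TargetAmplicon:
    """A random reference amplicon with a central exon and canonical
    splice dinucleotides written into the flanks."""
    if length < 2 * exon_margin + 3:
        raise ValueError("amplicon too short for the requested exon margin")
    seq = list(rng.choice(list(_BASES), size=length))
    exon = (exon_margin, length - exon_margin)
    sites: Tuple[SpliceSite, ...] = ()
    if with_splice_sites:
        if exon_margin < 2:
            raise ValueError("need exon_margin >= 2 for splice sites")
        seq[exon[0] - 2:exon[0]] = ["A", "G"]
        seq[exon[1]:exon[1] + 2] = ["G", "T"]
        sites = (SpliceSite(exon[0] - 2, exon[0], "acceptor"),
                 SpliceSite(exon[1], exon[1] + 2, "donor"))
    return TargetAmplicon(amplicon_id, "".join(seq), exon, frame_offset,
                          cds_strand, sites)


def simulate_genotypes(cfg: SimConfig,
                       rng: np.random.Generator) -> Dict[int, List[GenotypeVariant]]:
    """Per-fish heterozygous variant sets.

    Planted variants go to their named fish (one allele).  Random induced
    mutations are drawn per fish per amplicon at ``enu_rate`` with
    substitution classes from the ENU spectrum.  Founder polymorphisms are
    assigned per fish under Hardy-Weinberg at their population frequency.
    Draw order (fixed): planted, then ENU per amplicon, then polymorphisms.
    """
    genotypes: Dict[int, List[GenotypeVariant]] = {}

    for pv in cfg.planted_variants:
        genotypes.setdefault(pv.fish_id, []).append(GenotypeVariant(
            pv.amplicon_id, pv.position, pv.alt.upper(), 1, PLANTED))

    if cfg.enu_rate > 0:
        spectrum = enu_spectrum_weights()
        for amp in cfg.amplicons:
            counts = rng.poisson(cfg.enu_rate, size=cfg.design.n_fish)
            for fish in np.flatnonzero(counts):
                for _ in range(int(counts[fish])):
                    pos = int(rng.integers(0, len(amp)))
                    ref = amp.sequence[pos].upper()
                    if ref not in _BASES:
                        continue
                    alts = [a for a in _BASES if a != ref]
                    w = np.array([spectrum[(ref, a)] for a in alts])
                    if w.sum() == 0:
                        continue
                    alt = str(rng.choice(alts, p=w / w.sum()))
                    genotypes.setdefault(int(fish), []).append(GenotypeVariant(
                        amp.amplicon_id, pos, alt, 1, ENU))

    for poly in cfg.polymorphisms:
        copies = rng.binomial(cfg.design.ploidy, poly.frequency,
                              size=cfg.design.n_fish)
        for fish in np.flatnonzero(copies):
            genotypes.setdefault(int(fish), []).append(GenotypeVariant(
                poly.amplicon_id, poly.position, poly.alt.upper(),
                int(copies[fish]), POLYMORPHISM))
    return genotypes


@dataclass
class PoolReads:
    """Simulated reads for one amplicon in one pool, plus ground truth."""

    amplicon_id: str
    pool_id: str
    S1: np.ndarray  # (n, read_len) uint8 base codes, mate 1
    Q1: np.ndarray
    S2: np.ndarray  # mate 2 in sequencing orientation
    Q2: np.ndarray
    template_variants: Dict[Tuple[int, str], float]  # (pos, alt) -> allele freq
    pcr_lineages: List[Tuple[int, str, float]]       # (pos, alt, lineage freq)
    pcr_read_errors: Set[Tuple[int, str]]

    @property
    def n_pairs(self) -> int:
        return self.S1.shape[0]

    @property
    def pcr_positions(self) -> Set[Tuple[int, str]]:
        return {(p, a) for p, a, _ in self.pcr_lineages} | set(self.pcr_read_errors)

    def read_ids(self) -> List[str]:
        return [f"{self.amplicon_id}:{self.pool_id}:{i}" for i in range(self.n_pairs)]


def _pool_allele_table(cfg: SimConfig, genotypes, fish_ids: Sequence[int],
                       amplicon: TargetAmplicon,
                       rng: np.random.Generator) -> Tuple[Dict[int, List[Tuple[int, int]]], int]:
    """Map allele index -> substitutions, for one pool and amplicon.

    Allele indices run over the pool's fish in order, ``ploidy`` alleles per
    fish; a variant with c copies is placed on c distinct randomly chosen
    alleles of its carrier.
    """
    ploidy = cfg.design.ploidy
    table: Dict[int, List[Tuple[int, int]]] = {}
    for slot, fish in enumerate(fish_ids):
        for gv in genotypes.get(fish, []):
            if gv.amplicon_id != amplicon.amplicon_id:
                continue
            which = rng.choice(ploidy, size=min(gv.copies, ploidy), replace=False)
            alt_code = int(encode(gv.alt)[0])
            for w in np.sort(which):
                table.setdefault(slot * ploidy + int(w), []).append(
                    (gv.position, alt_code))
    return table, len(fish_ids) * ploidy


def simulate_pool_reads(cfg: SimConfig, fish_ids: Sequence[int],
                        amplicon: TargetAmplicon, rng: np.random.Generator,
                        pool_id: str = "0",
                        depth: Optional[int] = None,
                        genotypes: Optional[Dict[int, List[GenotypeVariant]]] = None,
                        jackpot_cutoff: float = 50.0) -> PoolReads:
    """Simulate the read pairs for one amplicon in one pool.

    Each pair draws a template allele uniformly from the pool's alleles
    (optionally biased per fish), inherits any early-cycle PCR jackpot
    lineage on that allele with probability 2^(1-c), picks up independent
    late-cycle PCR errors, and is read from both ends with independent
    per-base sequencing errors.  Fragments shorter than the read are padded
    with adapter sequence (exercising read-through trimming in the merge).
    """
    if genotypes is None:
        genotypes = simulate_genotypes(cfg, rng)
    table, n_alleles = _pool_allele_table(cfg, genotypes, fish_ids, amplicon, rng)
    n = int(depth if depth is not None else cfg.depth_per_pool)
    L = len(amplicon)
    ref = amplicon.codes

    # per-fish amplification bias -> allele draw weights
    disp = cfg.dispersion
    if disp is not None and disp.fish_sigma > 0:
        fish_w = np.exp(rng.normal(0.0, disp.fish_sigma, size=len(fish_ids)))
        allele_w = np.repeat(fish_w, cfg.design.ploidy)
        templates = rng.choice(n_alleles, size=n, p=allele_w / allele_w.sum())
    else:
        templates = rng.integers(0, n_alleles, size=n)

    frags = np.tile(ref, (n, 1))
    template_variants: Dict[Tuple[int, str], float] = {}
    carriers: Dict[Tuple[int, int], List[int]] = {}
    for allele, subs in table.items():
        for pos, alt_code in subs:
            carriers.setdefault((pos, alt_code), []).append(allele)
    for (pos, alt_code), alleles in sorted(carriers.items()):
        rows = np.isin(templates, alleles)
        frags[rows, pos] = alt_code
        template_variants[(pos, _BASES[alt_code])] = len(alleles) / n_alleles

    # --- PCR error layer -------------------------------------------------
    pcr_lineages: List[Tuple[int, str, float]] = []
    pcr_read_errors: Set[Tuple[int, str]] = set()
    e_pcr, cycles = cfg.pcr_error_rate, cfg.pcr_cycles
    if e_pcr > 0 and cycles > 0:
        # early cycles: few template lineages -> shared ("jackpot") errors;
        # once the molecule count is far above the sampled depth a lineage
        # is effectively private to one read and is folded into a per-read
        # late-error rate
        c_split = cycles + 1
        for c in range(1, cycles + 1):
            if n_alleles * 2.0 ** (c - 1) >= jackpot_cutoff * n:
                c_split = c
                break
        for c in range(1, c_split):
            n_events = rng.poisson(n_alleles * 2.0 ** (c - 1) * L * e_pcr)
            for _ in range(int(n_events)):
                allele = int(rng.integers(0, n_alleles))
                pos = int(rng.integers(0, L))
                base_here = int(ref[pos])
                for (vp, va), al in carriers.items():
                    if vp == pos and allele in al:
                        base_here = va
                alt_code = (base_here + int(rng.integers(1, 4))) % 4
                inherit = 2.0 ** (-(c - 1))
                rows = np.flatnonzero(templates == allele)
                hit = rows[rng.random(rows.size) < inherit]
                frags[hit, pos] = alt_code
                pcr_lineages.append((pos, _BASES[alt_code],
                                     2.0 ** (-(c - 1)) / n_alleles))
        late_rate = L * e_pcr * (cycles - c_split + 1)
        if late_rate > 0:
            hit_reads = np.flatnonzero(rng.random(n) < late_rate)
            for r in hit_reads:
                pos = int(rng.integers(0, L))
                alt_code = (int(frags[r, pos]) + int(rng.integers(1, 4))) % 4
                frags[r, pos] = alt_code
                pcr_read_errors.add((pos, _BASES[alt_code]))

    # --- read layout ------------------------------------------------------
    rl = cfg.read_len
    if L >= rl:
        S1 = frags[:, :rl].copy()
        S2 = COMPLEMENT[frags[:, ::-1]][:, :rl].copy()
    else:
        pad = np.tile(encode((ADAPTER * (rl // len(ADAPTER) + 1))[:rl - L]), (n, 1))
        S1 = np.concatenate([frags, pad], axis=1)
        S2 = np.concatenate([COMPLEMENT[frags[:, ::-1]], pad], axis=1)

    # --- sequencing errors ------------------------------------------------
    Q1 = np.full(S1.shape, cfg.q_high, dtype=np.int16)
    Q2 = np.full(S2.shape, cfg.q_high, dtype=np.int16)
    e = cfg.seq_error_rate
    if e > 0:
        for S, Q in ((S1, Q1), (S2, Q2)):
            mask = rng.random(S.shape) < e
            shift = rng.integers(1, 4, size=int(mask.sum()))
            S[mask] = (S[mask] + shift) % 4
            Q[mask] = cfg.q_low

    return PoolReads(amplicon.amplicon_id, str(pool_id), S1, Q1, S2, Q2,
                     template_variants, pcr_lineages, pcr_read_errors)


def write_truth(cfg: SimConfig,
                genotypes: Dict[int, List[GenotypeVariant]],
                plans: Optional[Sequence[DeconvolutionPlan]] = None):
    """Truth table of all simulated variants as a DataFrame.

    One row per (fish, variant) with the carrier's pool, the expected
    in-pool allele frequency, and the variant's origin, enabling automated
    sensitivity / false-positive scoring against pipeline output.
    Positions are reported 1-based, like the call tables.
    """
    import pandas as pd

    if plans is None:
        plans = build_pools(cfg.design)
    pool_of = {}
    pool_size = {}
    for p in plans:
        pool_size[p.superpool_id] = p.n_fish
        for f in p.fish_ids:
            pool_of[f] = p.superpool_id
    rows = []
    for fish in sorted(genotypes):
        for gv in genotypes[fish]:
            amp = cfg.amplicon(gv.amplicon_id)
            pool = pool_of[fish]
            rows.append({
                "fish_id": fish,
                "amplicon_id": gv.amplicon_id,
                "pos_1based": gv.position + 1,
                "ref": amp.sequence[gv.position].upper(),
                "alt": gv.alt,
                "copies": gv.copies,
                "kind": gv.kind,
                "pool_id": pool,
                "expected_pool_freq": gv.copies / (pool_size[pool] * cfg.design.ploidy),
            })
    cols = ["fish_id", "amplicon_id", "pos_1based", "ref", "alt", "copies",
            "kind", "pool_id", "expected_pool_freq"]
    return pd.DataFrame(rows, columns=cols)


def simulate_library(cfg: SimConfig):
    """Simulate every (pool, amplicon) of the library.

    Returns ``(plans, genotypes, {(pool_id, amplicon_id): PoolReads})``.
    Depth dispersion, when enabled, draws one median-preserving lognormal
    factor per fragment and one per pool.  Draw order: genotypes, then
    dispersion factors, then pools in order, amplicons in order.
    """
    rng = np.random.default_rng(cfg.seed)
    plans = build_pools(cfg.design)
    genotypes = simulate_genotypes(cfg, rng)
    disp = cfg.dispersion
    if disp is not None:
        frag_f = np.exp(rng.normal(0.0, disp.fragment_sigma, size=len(cfg.amplicons)))
        pool_f = np.exp(rng.normal(0.0, disp.pool_sigma, size=len(plans)))
    else:
        frag_f = np.ones(len(cfg.amplicons))
        pool_f = np.ones(len(plans))
    out = {}
    for p in plans:
        for ai, amp in enumerate(cfg.amplicons):
            depth = max(1, int(round(cfg.depth_per_pool
                                     * frag_f[ai] * pool_f[p.superpool_id])))
            out[(p.superpool_id, amp.amplicon_id)] = simulate_pool_reads(
                cfg, p.fish_ids, amp, rng, pool_id=str(p.superpool_id),
                depth=depth, genotypes=genotypes)
    return plans, genotypes, out
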