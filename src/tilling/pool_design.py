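"""Pooling arithmetic for a TILLING library.

A mutagenized library of ``n_fish`` diploid individuals is pooled twice:
consecutive fish are combined into small *subpools* (default 6 fish, the
unit genotyped by high-resolution melt during deconvolution), and
consecutive subpools are combined into *superpools* (default 48 subpools =
288 fish), each sequenced under a single barcode.  A heterozygous mutation
unique to one fish is then expected at allele frequency 1/(2 * 288) = 1/576
in exactly one superpool, and the minimum sequencing depth needed to see
every allele ``reads_per_allele`` times is ``n_fish_in_pool * ploidy *
reads_per_allele`` (2,880 reads for a full 288-fish pool at 5 reads per
allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Sequence


@dataclass(frozen=True)
class LibraryDesign:
    """Parameters of the pooled library.

    Attributes
    ----------
    n_fish:
        Number of mutagenized individuals in the library.
    ploidy:
        Alleles per individual (2 for a diploid).
    subpool_size:
        Individuals per first-tier pool (the deconvolution unit).
    subpools_per_superpool:
        First-tier pools combined into one sequencing pool.
    reads_per_allele:
        Minimum informative reads demanded per allele when setting the
        per-position coverage floor.
    """

    n_fish: int
    ploidy: int = 2
    subpool_size: int = 6
    subpools_per_superpool: int = 48
    reads_per_allele: int = 5

    def __post_init__(self) -> None:
        for name in ("n_fish", "ploidy", "subpool_size",
                     "subpools_per_superpool", "reads_per_allele"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")

    @property
    def n_alleles(self) -> int:
        """Total alleles in the library (the WT denominator of a singleton)."""
        return self.n_fish * self.ploidy

    @property
    def superpool_size(self) -> int:
        """Fish per full superpool."""
        return self.subpool_size * self.subpools_per_superpool


@dataclass(frozen=True)
class DeconvolutionPlan:
    """One superpool and the subpool/fish structure underneath it."""

    superpool_id: int
    subpool_ids: tuple
    fish_ids_by_subpool: tuple  # tuple of tuples, parallel to subpool_ids

    @property
    def n_fish(self) -> int:
        return sum(len(f) for f in self.fish_ids_by_subpool)

    @property
    def fish_ids(self) -> tuple:
        return tuple(f for sub in self.fish_ids_by_subpool for f in sub)


def min_depth(design: LibraryDesign, pool_n_fish: int | None = None) -> int:
    """Minimum reads per position for full screening of one pool.

    ``pool_n_fish * ploidy * reads_per_allele``; for the default design and a
    full 288-fish pool this is 2,880 reads, i.e. 5 reads per allele assuming
    equal amplification of every allele in the pool.  Short pools use their
    actual fish count (a 192-fish pool needs 1,920 reads).
    """
    if pool_n_fish is None:
        pool_n_fish = design.superpool_size
    if not isinstance(pool_n_fish, int) or isinstance(pool_n_fish, bool) or pool_n_fish < 1:
        raise ValueError(f"pool_n_fish must be a positive integer, got {pool_n_fish!r}")
    return pool_n_fish * design.ploidy * design.reads_per_allele


def expected_carrier_frequency(pool_n_fish: int, ploidy: int = 2,
                               carrier_alleles: int = 1) -> float:
    """Expected allele frequency of a variant carried on ``carrier_alleles``
    alleles in a pool of ``pool_n_fish`` individuals.

    A mutation heterozygous in a single fish of a 288-fish pool is expected
    at 1/576; across a 9,024-fish library the ratio is 1:18,048 alleles.
    """
    if pool_n_fish < 1 or ploidy < 1:
        raise ValueError("pool_n_fish and ploidy must be >= 1")
    total = pool_n_fish * ploidy
    if not 1 <= carrier_alleles <= total:
        raise ValueError(
            f"carrier_alleles must be in [1, {total}], got {carrier_alleles}")
    return carrier_alleles / total


def build_pools(design: LibraryDesign) -> List[DeconvolutionPlan]:
    """Construct the subpool/superpool plan for a library.

    Consecutive fish fill subpools in order and consecutive subpools fill
    superpools in order.  When the trailing remainder of subpools would be
    smaller than half a superpool, the last full superpool is rebalanced
    with the remainder into two near-equal superpools, so a 9,024-fish
    library (1,504 six-fish subpools, 48 subpools per superpool) yields
    30 full 288-fish superpools plus two 192-fish superpools rather than a
    single 96-fish runt.
    """
    if design.n_fish % design.subpool_size != 0:
        raise ValueError(
            f"n_fish ({design.n_fish}) must be divisible by subpool_size "
            f"({design.subpool_size}); pools are built from consecutive "
            "complete subpools")
    n_sub = design.n_fish // design.subpool_size
    sps = design.subpools_per_superpool

    n_full, r = divmod(n_sub, sps)
    sizes: List[int]
    if r == 0:
        sizes = [sps] * n_full
    elif n_full == 0:
        sizes = [r]
    elif r < (sps + 1) // 2:
        # rebalance the last full superpool with the remainder
        pooled = sps + r
        sizes = [sps] * (n_full - 1) + [(pooled + 1) // 2, pooled // 2]
    else:
        sizes = [sps] * n_full + [r]

    plans: List[DeconvolutionPlan] = []
    sub_cursor = 0
    for sp_id, size in enumerate(sizes):
        sub_ids = tuple(range(sub_cursor, sub_cursor + size))
        fish = tuple(
            tuple(range(s * design.subpool_size, (s + 1) * design.subpool_size))
            for s in sub_ids)
        plans.append(DeconvolutionPlan(sp_id, sub_ids, fish))
        sub_cursor += size
    return plans


def deconvolution_candidates(plans: Sequence[DeconvolutionPlan],
                             superpool_id: int,
                             stage: Literal["subpools", "individuals"],
                             subpool_id: int | None = None) -> List[int]:
    """IDs to genotype at one deconvolution stage.

    ``stage='subpools'`` lists the superpool's subpools (48 HRM reactions for
    a full pool); ``stage='individuals'`` lists the fish of one named subpool
    (the 6 single-fish HRM reactions of the second round).
    """
    by_id = {p.superpool_id: p for p in plans}
    if superpool_id not in by_id:
        raise KeyError(f"unknown superpool id {superpool_id}")
    plan = by_id[superpool_id]
    if stage == "subpools":
        return list(plan.subpool_ids)
    if stage == "individuals":
        if subpool_id is None:
            raise ValueError("stage='individuals' requires subpool_id")
        try:
            idx = plan.subpool_ids.index(subpool_id)
        except ValueError:
            raise KeyError(
                f"subpool {subpool_id} is not in superpool {superpool_id}") from None
        return list(plan.fish_ids_by_subpool[idx])
    raise ValueError(f"unknown stage {stage!r}")


def pool_of_fish(plans: Sequence[DeconvolutionPlan], fish_id: int) -> int:
    """Superpool id containing a given fish."""
    for p in plans:
        for sub in p.fish_ids_by_subpool:
            if fish_id in sub:
                return p.superpool_id
    raise KeyError(f"fish {fish_id} is not in any superpool")
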