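"""Screening of raw variant calls.

Single-base variants in a pooled amplicon have three origins: induced
mutations (one heterozygous fish per library, expected at F ~ 1/576 in a
288-fish pool), pre-existing founder polymorphisms (much more frequent),
and errors introduced during PCR (concentrated at low frequency, with rare
early-cycle "jackpot" exceptions).  The screen encodes the empirical
frequency window: calls at F > 1/100 are excluded as polymorphisms, calls
at F < 1/1000 as PCR noise, and the rest pass as candidate induced
mutations, provided the position had the minimum coverage (2,880 reads for
a full 288-fish pool = 5 reads per allele).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .call import PoolPileup, VariantCall

PASS = "pass"
POLYMORPHISM = "polymorphism"
PCR_NOISE = "pcr_noise"
LOW_COVERAGE = "low_coverage"

STATUSES = (PASS, POLYMORPHISM, PCR_NOISE, LOW_COVERAGE)


@dataclass(frozen=True)
class ScreenConfig:
    """Frequency window and coverage floor.

    The pass band is ``f_min <= F <= f_max`` (1/1000 to 1/100 by default).
    The thresholds are written as strict inequalities in the frequency
    argument, but measured F on finite counts essentially never lands
    exactly on a boundary; equality is treated as passing by default so a
    theoretical singleton is never dropped at marginal depth
    (``boundary_inclusive=False`` flips to strict).
    """

    f_max: float = 1.0 / 100.0
    f_min: float = 1.0 / 1000.0
    min_depth: int = 2880
    require_deleterious: bool = False
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max <= 1:
            raise ValueError("need 0 < f_min < f_max <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def apply_screen(calls: Sequence[VariantCall],
                 cfg: ScreenConfig = ScreenConfig()) -> List[VariantCall]:
    """Set ``filter_status`` on every call and return the same list.

    Coverage is checked first (a position below ``min_depth`` is not
    considered screened at all), then the polymorphism ceiling, then the
    PCR-noise floor; everything else passes.
    """
    for c in calls:
        if c.total_reads < cfg.min_depth:
            c.filter_status = LOW_COVERAGE
        elif (c.frequency > cfg.f_max if cfg.boundary_inclusive
              else c.frequency >= cfg.f_max):
            c.filter_status = POLYMORPHISM
        elif (c.frequency < cfg.f_min if cfg.boundary_inclusive
              else c.frequency <= cfg.f_min):
            c.filter_status = PCR_NOISE
        else:
            c.filter_status = PASS
    return list(calls)


def passing(calls: Iterable[VariantCall]) -> List[VariantCall]:
    return [c for c in calls if c.filter_status == PASS]


def flag_recurrent(calls: Sequence[VariantCall], min_pools: int = 2) -> Dict[
        Tuple[str, int, str], int]:
    """Optional cross-pool recurrence flag (off by default in the screen).

    Returns, for each (amplicon, position, alt) passing in at least
    ``min_pools`` distinct pools, the number of pools involved.  A genuine
    induced mutation is unique to one fish, hence one pool; recurrence
    suggests a polymorphism below the frequency ceiling.
    """
    pools: Dict[Tuple[str, int, str], set] = {}
    for c in calls:
        if c.filter_status == PASS:
            pools.setdefault((c.amplicon_id, c.position, c.alt_base),
                             set()).add(c.pool_id)
    return {k: len(v) for k, v in pools.items() if len(v) >= min_pools}


def fully_screened(pileup: PoolPileup, min_depth: int = 2880) -> bool:
    """True when every position of the fragment meets the coverage floor
    in this pool."""
    return bool(np.all(pileup.depth >= min_depth))


def screen_summary(calls: Sequence[VariantCall],
                   pileups: Sequence[PoolPileup] = (),
                   min_depth: int = 2880) -> pd.DataFrame:
    """Tally of filter statuses per amplicon per pool.

    One row per (amplicon, pool) with a column per status plus ``total``;
    if pileups are provided, a ``fully_screened`` column marks fragment/pool
    units whose every position met ``min_depth``.
    """
    counts: Counter = Counter()
    for c in calls:
        counts[(c.amplicon_id, c.pool_id, c.filter_status)] += 1
    keys = sorted({(a, p) for a, p, _ in counts}
                  | {(pp.amplicon_id, pp.pool_id) for pp in pileups})
    rows = []
    screened = {(pp.amplicon_id, pp.pool_id): fully_screened(pp, min_depth)
                for pp in pileups}
    for amp, pool in keys:
        row = {"amplicon_id": amp, "pool_id": pool}
        for st in STATUSES:
            row[st] = counts.get((amp, pool, st), 0)
        row["total"] = sum(row[st] for st in STATUSES)
        if pileups:
            row["fully_screened"] = screened.get((amp, pool), False)
        rows.append(row)
    return pd.DataFrame(rows)


def validation_rate(confirmed_by_bin: Sequence[int],
                    attempted_by_bin: Sequence[int]) -> Tuple[List[float], float]:
    """Percent of attempted validations confirmed, per frequency bin and
    pooled over all bins.

    For the reference screen's worked example - 30/37 confirmed in the (1/100,
    1/576] bin and 18/41 in the (1/576, 1/1000] bin - this returns
    (81.1%, 43.9%) per bin and 61.5% pooled.  A bin with zero attempts is
    reported as NaN.
    """
    if len(confirmed_by_bin) != len(attempted_by_bin):
        raise ValueError("confirmed and attempted must have the same length")
    per_bin: List[float] = []
    for conf, att in zip(confirmed_by_bin, attempted_by_bin):
        if conf > att:
            raise ValueError("confirmed cannot exceed attempted")
        per_bin.append(100.0 * conf / att if att > 0 else float("nan"))
    total_att = sum(attempted_by_bin)
    pooled = 100.0 * sum(confirmed_by_bin) / total_att if total_att else float("nan")
    return per_bin, pooled


def call_reduction_ratio(unmerged_calls: int, merged_calls: int) -> float:
    """How many times more pass-band calls an unmerged (per-mate) analysis
    makes than the merged pipeline; the reference screen saw 56,467 / 1,115 =
    50.6x."""
    if merged_calls <= 0:
        return float("inf") if unmerged_calls > 0 else float("nan")
    return unmerged_calls / merged_calls


def noise_filtered_fraction(unmerged_calls: int, merged_calls: int) -> float:
    """Fraction of unmerged pass-band calls removed by the merge filter
    ((56,467 - 1,115) / 56,467 = 98%)."""
    if unmerged_calls <= 0:
        return float("nan")
    return (unmerged_calls - merged_calls) / unmerged_calls
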