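"""End-to-end orchestration: merge -> assign -> pileup -> call -> screen ->
classify, per pool, plus report files.

The pipeline consumes pre-demultiplexed per-pool FASTQ pairs (one R1/R2
pair per sequencing pool), the reference FASTA and its annotation TSV, and
emits per-pool call tables, screen summaries, merge statistics, a
library-wide candidate list (pass-band calls, predicted-deleterious
first), and a deconvolution worksheet per candidate listing the subpools
and fish to genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from ._seq import revcomp
from .call import (Assignment, PoolPileup, TargetAmplicon, VariantCall,
                   assign_reads, build_pileup, call_variants)
from .pele import MergeConfig, merge_pairs
from .podata import enumerate_deleterious
from .pool_design import LibraryDesign, build_pools, deconvolution_candidates
from .screen import ScreenConfig, apply_screen, passing, screen_summary

log = logging.getLogger("tilling")

DELETERIOUS = ("nonsense", "splice")


@dataclass
class PipelineConfig:
    refs_fasta: str
    annotation: str
    pools: Dict[str, Tuple[str, str]]  # pool_id -> (R1 path, R2 path)
    out_dir: str
    merge: MergeConfig = field(default_factory=MergeConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    design: Optional[LibraryDesign] = None
    no_merge: bool = False           # ablation: per-mate analysis, no PELE
    emit_vcf: bool = False
    max_mismatch_frac: float = 0.10

    def __post_init__(self) -> None:
        if len(set(self.pools)) != len(self.pools):
            raise ValueError("pool ids must be unique")


def load_pipeline_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (keys mirror the dataclass;
    ``merge``, ``screen`` and ``design`` are nested mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pools = {str(k): (v["r1"], v["r2"]) for k, v in raw.get("pools", {}).items()}
    kwargs = dict(
        refs_fasta=raw["refs"], annotation=raw["annotation"], pools=pools,
        out_dir=raw.get("out_dir", "."))
    if "merge" in raw:
        kwargs["merge"] = MergeConfig(**raw["merge"])
    if "screen" in raw:
        kwargs["screen"] = ScreenConfig(**raw["screen"])
    if "design" in raw:
        kwargs["design"] = LibraryDesign(**raw["design"])
    for key in ("no_merge", "emit_vcf", "max_mismatch_frac"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


@dataclass
class PoolResult:
    pool_id: str
    merge_stats: Dict[str, object]
    pileups: List[PoolPileup]
    calls: List[VariantCall]
    n_unassigned: int


@dataclass
class PipelineReport:
    pools: List[PoolResult]
    calls: pd.DataFrame
    candidates: pd.DataFrame
    summary: pd.DataFrame
    merge_stats: pd.DataFrame


def _pool_reads(cfg: PipelineConfig, r1_path, r2_path, pool_id: str):
    """Load one pool and produce the read set to align: merged consensus
    reads, or (ablation) both raw mates with mate 2 reverse-complemented."""
    ids1, S1, Q1 = tio.read_fastq_arrays(r1_path)
    ids2, S2, Q2 = tio.read_fastq_arrays(r2_path)
    if len(ids1) != len(ids2):
        raise tio.FormatError(
            f"pool {pool_id}: R1 has {len(ids1)} reads but R2 has {len(ids2)}")
    stats: Dict[str, object] = {"pool_id": pool_id, "pairs_in": len(ids1)}
    if len(ids1) == 0:
        stats.update(merged=0, rejected_identity=0, rejected_no_overlap=0,
                     discard_fraction=0.0)
        return [], stats
    if cfg.no_merge:
        reads = [s for s in S1] + [revcomp(s) for s in S2]
        stats.update(merged=len(reads), rejected_identity=0,
                     rejected_no_overlap=0, discard_fraction=0.0)
        return reads, stats
    batch = merge_pairs(S1, Q1, S2, Q2, cfg.merge)
    stats.update(batch.counts())
    stats["discard_fraction"] = batch.discard_fraction
    reads = [s for s in batch.seqs if s is not None]
    return reads, stats


def run_pool(cfg: PipelineConfig, pool_id: str,
             amplicons: Sequence[TargetAmplicon]) -> PoolResult:
    r1, r2 = cfg.pools[pool_id]
    for p in (r1, r2):
        if not Path(p).exists():
            raise FileNotFoundError(f"pool {pool_id}: missing FASTQ {p}")
    reads, stats = _pool_reads(cfg, r1, r2, pool_id)
    assignments: List[Optional[Assignment]]
    assignments = assign_reads(reads, list(amplicons),
                               cfg.max_mismatch_frac) if reads else []
    n_unassigned = sum(a is None for a in assignments)
    pileups: List[PoolPileup] = []
    calls: List[VariantCall] = []
    for amp in amplicons:
        pp = build_pileup(reads, assignments, amp, pool_id)
        pileups.append(pp)
        calls.extend(call_variants(pp, amp))
    apply_screen(calls, cfg.screen)
    catalogs = {a.amplicon_id: enumerate_deleterious(a) for a in amplicons}
    amp_by_id = {a.amplicon_id: a for a in amplicons}
    from .podata import classify_call

    for c in calls:
        classify_call(c, catalogs[c.amplicon_id], amp_by_id[c.amplicon_id])
    return PoolResult(pool_id, stats, pileups, calls, n_unassigned)


def _candidate_frame(calls: Sequence[VariantCall], cfg: PipelineConfig) -> pd.DataFrame:
    cands = passing(calls)
    if cfg.screen.require_deleterious:
        cands = [c for c in cands if c.consequence in DELETERIOUS]
    cands = sorted(cands, key=lambda c: (c.consequence not in DELETERIOUS,
                                         c.amplicon_id, c.position, c.alt_base))
    return tio.calls_to_frame(cands)


def _write_worksheets(out_dir: Path, candidates: pd.DataFrame,
                      design: LibraryDesign) -> None:
    """One deconvolution worksheet per candidate: the subpools of its pool
    (first HRM round) and the fish of each subpool (second round).
    Labels are 1-based to match plate conventions."""
    plans = build_pools(design)
    by_id = {p.superpool_id: p for p in plans}
    for _, row in candidates.iterrows():
        try:
            sp = int(row["pool_id"])
        except (TypeError, ValueError):
            continue
        if sp not in by_id:
            continue
        plan = by_id[sp]
        rows = []
        for sub, fish in zip(plan.subpool_ids, plan.fish_ids_by_subpool):
            rows.append({
                "superpool": sp + 1,
                "subpool": sub + 1,
                "fish": ",".join(str(f + 1) for f in fish),
            })
        name = (f"worksheet_pool{sp + 1}_{row['amplicon_id']}"
                f"_{row['pos_1based']}{row['alt']}.tsv")
        pd.DataFrame(rows).to_csv(out_dir / name, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run every pool and write the report bundle under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    amplicons = tio.read_annotation(cfg.annotation, cfg.refs_fasta)
    log.info("screen thresholds: min_identity=%g f_max=%g f_min=%g min_depth=%d",
             cfg.merge.min_identity, cfg.screen.f_max, cfg.screen.f_min,
             cfg.screen.min_depth)

    results = [run_pool(cfg, pool_id, amplicons) for pool_id in sorted(cfg.pools)]

    all_calls: List[VariantCall] = [c for r in results for c in r.calls]
    all_pileups = [pp for r in results for pp in r.pileups]
    calls_df = tio.calls_to_frame(all_calls)
    calls_df.to_csv(out_dir / "calls.tsv", sep="\t", index=False,
                    float_format="%.6g")
    for r in results:
        tio.write_calls(out_dir / f"calls_pool{r.pool_id}.tsv", r.calls)
        if cfg.emit_vcf:
            tio.write_vcf(out_dir / f"calls_pool{r.pool_id}.vcf", r.calls,
                          amplicons, sample=f"POOL{r.pool_id}")

    merge_df = pd.DataFrame([r.merge_stats for r in results])
    merge_df.to_csv(out_dir / "merge_stats.tsv", sep="\t", index=False,
                    float_format="%.6g")
    summary = screen_summary(all_calls, all_pileups, cfg.screen.min_depth)
    summary.to_csv(out_dir / "screen_summary.tsv", sep="\t", index=False)

    candidates = _candidate_frame(all_calls, cfg)
    candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False,
                      float_format="%.6g")
    if cfg.design is not None and len(candidates):
        _write_worksheets(out_dir, candidates, cfg.design)
    return PipelineReport(results, calls_df, candidates, summary, merge_df)
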