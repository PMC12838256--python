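"""End-to-end orchestration of the sweep scan.

Chains the stages in their fixed order: variant filtering -> per-site
Weir-Cockerham components and windowed statistics -> top-1% dual-statistic
outlier calling -> ±50 kb candidate-gene annotation -> gene-set
intersection. Each stage remains independently usable; this module only
wires them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import genes_near_snps
from .containers import GeneRecord, SiteTable
from .filters import FilterThresholds, filter_table
from .popgen import window_scan
from .scan import SweepRegion, call_outliers, intersect_candidates, snps_in_windows


@dataclass
class PipelineResult:
    filtered: SiteTable
    filter_summary: pd.DataFrame
    components: pd.DataFrame
    window_stats: pd.DataFrame
    outliers: SweepRegion
    fst_snps: pd.DataFrame
    pi_snps: pd.DataFrame
    fst_candidates: pd.DataFrame
    pi_candidates: pd.DataFrame
    intersection: dict


def run_sweep_pipeline(
    table: SiteTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    genes: Sequence[GeneRecord] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    window_bp: int = 100_000,
    step_bp: int = 50_000,
    quantile: float = 0.99,
    flank_bp: int = 50_000,
    thresholds: FilterThresholds | None = None,
    chromosome_allowlist: Sequence[str] | None = None,
) -> PipelineResult:
    """Run filtering, scanning, outlier calling and (optionally) annotation."""
    filtered, summary = filter_table(table, thresholds=thresholds)
    components, stats = window_scan(
        filtered, case_ids, control_ids, chrom_lengths, window_bp, step_bp
    )
    outliers = call_outliers(stats, quantile=quantile)
    fst_snps = snps_in_windows(filtered.chrom, filtered.pos, outliers.fst_windows)
    pi_snps = snps_in_windows(filtered.chrom, filtered.pos, outliers.pi_windows)
    outliers.selected_snps = snps_in_windows(
        filtered.chrom, filtered.pos, outliers.shared_windows
    )
    empty = pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "n_supporting_snps"]
    )
    if genes:
        fst_candidates = genes_near_snps(
            fst_snps, genes, flank_bp, chromosome_allowlist
        )
        pi_candidates = genes_near_snps(pi_snps, genes, flank_bp, chromosome_allowlist)
        intersection = intersect_candidates(
            set(fst_candidates["gene_id"]), set(pi_candidates["gene_id"])
        )
    else:
        fst_candidates, pi_candidates = empty, empty.copy()
        intersection = intersect_candidates(set(), set())
    return PipelineResult(
        filtered=filtered,
        filter_summary=summary,
        components=components,
        window_stats=stats,
        outliers=outliers,
        fst_snps=fst_snps,
        pi_snps=pi_snps,
        fst_candidates=fst_candidates,
        pi_candidates=pi_candidates,
        intersection=intersection,
    )
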