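"""Top-1% dual-statistic outlier calling and candidate intersection.

Windows in the upper 1% tail of the empirical FST distribution and of the
pi-ratio distribution (computed over non-NA windows, linear-interpolation
quantile) are flagged separately; windows extreme in BOTH are the putative
selection signals. Ties at the threshold are all kept (selection rule is
``statistic >= threshold``), which is conservative for candidate discovery.
Candidate genes found for each statistic are intersected at the gene level,
with the three-part breakdown (FST-only / pi-only / shared) reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SweepRegion:
    """Outlier windows, their intersection, realized cutoffs, selected SNPs."""

    fst_windows: pd.DataFrame
    pi_windows: pd.DataFrame
    shared_windows: pd.DataFrame
    thresholds: dict[str, float]
    selected_snps: pd.DataFrame | None = None  # chrom, pos inside shared windows


def empirical_threshold(values: np.ndarray, quantile: float) -> float:
    """Upper-tail cutoff: linear-interpolation empirical quantile."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("no rankable windows")
    return float(np.quantile(values, quantile, method="linear"))


def call_outliers(
    windows: pd.DataFrame,
    quantile: float = 0.99,
    statistics: tuple[str, str] = ("fst", "pi_ratio"),
) -> SweepRegion:
    """Flag top-tail outlier windows per statistic and their intersection.

    NA windows are never selected. Emits a warning when fewer than 100
    rankable windows are available (the empirical 99th percentile is then
    poorly resolved) and when all values tie at the threshold.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    thresholds: dict[str, float] = {}
    outliers: dict[str, pd.DataFrame] = {}
    for stat in statistics:
        values = windows[stat].to_numpy(dtype=float)
        n_rankable = int((~np.isnan(values)).sum())
        if n_rankable == 0:
            raise ValueError(f"no rankable windows for statistic {stat!r}")
        if n_rankable < 100:
            warnings.warn(
                f"only {n_rankable} rankable windows for {stat}; "
                f"the {quantile:.0%} quantile is poorly resolved",
                stacklevel=2,
            )
        cutoff = empirical_threshold(values, quantile)
        with np.errstate(invalid="ignore"):
            selected = values >= cutoff
        selected &= ~np.isnan(values)
        if selected.sum() == n_rankable and n_rankable > 1:
            warnings.warn(
                f"all {stat} values tie at the threshold; every window selected",
                stacklevel=2,
            )
        thresholds[stat] = cutoff
        outliers[stat] = windows[selected].reset_index(drop=True)

    key_cols = ["chrom", "start", "end"]
    fst_keys = set(map(tuple, outliers[statistics[0]][key_cols].to_numpy()))
    shared_mask = [
        tuple(row) in fst_keys for row in outliers[statistics[1]][key_cols].to_numpy()
    ]
    shared = outliers[statistics[1]][shared_mask].reset_index(drop=True)
    return SweepRegion(
        fst_windows=outliers[statistics[0]],
        pi_windows=outliers[statistics[1]],
        shared_windows=shared,
        thresholds=thresholds,
    )


def snps_in_windows(
    chrom: np.ndarray, pos: np.ndarray, windows: pd.DataFrame
) -> pd.DataFrame:
    """SNPs (1-based positions) falling inside any of the given windows."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    keep = np.zeros(len(pos), dtype=bool)
    for row in windows.itertuples():
        keep |= (chrom == row.chrom) & (pos - 1 >= row.start) & (pos - 1 < row.end)
    return pd.DataFrame({"chrom": chrom[keep], "pos": pos[keep]}).drop_duplicates(
        ignore_index=True
    )


def intersect_candidates(
    fst_genes: set[str], pi_genes: set[str]
) -> dict[str, object]:
    """Gene-level intersection of the two statistics' candidate sets.

    Returns the shared set plus the Venn breakdown (FST-only, pi-only,
    shared) and per-method counts.
    """
    fst_genes, pi_genes = set(fst_genes), set(pi_genes)
    shared = fst_genes & pi_genes
    if not shared and (fst_genes or pi_genes):
        warnings.warn("candidate gene sets are disjoint", stacklevel=2)
    return {
        "shared": shared,
        "fst_only": fst_genes - pi_genes,
        "pi_only": pi_genes - fst_genes,
        "n_fst": len(fst_genes),
        "n_pi": len(pi_genes),
        "n_shared": len(shared),
    }
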