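"""Robustness procedures for the imbalanced case/control design.

Two checks mirror the analysis plan for a 145-case / 30-control cohort:

* **Down-sampling concordance** — repeatedly draw ``n_target`` cases without
  replacement, rerun the windowed scan, and compare against the full-data
  scan via Spearman rank correlation (over windows non-NA in both runs) and
  top-1% outlier-window overlap. Overlap is reported both as Jaccard and as
  recall of the full-data outlier set, since "overlap" admits either reading.
* **Block jackknife** — delete contiguous 200 kb blocks chromosome-wise and
  recompute a genome-wide summary (ratio-of-sums FST, or the ratio of summed
  pi values); SE^2 = ((B-1)/B) * sum_j (theta_(-j) - theta_bar)^2 and the
  95% CI is the point estimate ± 1.96 SE. A 200 kb block exceeds a single
  100 kb window, so the jackknife targets genome-wide summaries rather than
  per-window values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import SiteTable
from .popgen import window_scan
from .scan import empirical_threshold


@dataclass
class DownsampleReport:
    """Per-iteration and summarized concordance between full and reduced scans."""

    iterations: pd.DataFrame  # one row per iteration
    summary: pd.DataFrame  # mean and percentile band per metric
    n_target: int
    n_iterations: int


@dataclass
class JackknifeReport:
    statistic: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_blocks: int


def _top_window_keys(stats: pd.DataFrame, column: str, quantile: float) -> set:
    values = stats[column].to_numpy(dtype=float)
    cutoff = empirical_threshold(values, quantile)
    with np.errstate(invalid="ignore"):
        mask = (values >= cutoff) & ~np.isnan(values)
    return set(map(tuple, stats.loc[mask, ["chrom", "start"]].to_numpy()))


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    both = ~(np.isnan(x) | np.isnan(y))
    if both.sum() < 2:
        return float("nan")
    x, y = x[both], y[both]
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant window statistic; Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def _overlap(full: set, sub: set) -> tuple[float, float]:
    union = full | sub
    jaccard = len(full & sub) / len(union) if union else float("nan")
    recall = len(full & sub) / len(full) if full else float("nan")
    return jaccard, recall


def downsample_concordance(
    table: SiteTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    n_target: int = 30,
    iterations: int = 100,
    seed: int = 0,
    window_bp: int = 100_000,
    step_bp: int = 50_000,
    quantile: float = 0.99,
    chrom_lengths: dict[str, int] | None = None,
) -> DownsampleReport:
    """Concordance of the windowed scan under case down-sampling.

    Each iteration samples ``n_target`` cases uniformly without replacement
    and recomputes all window statistics on the same window grid. Fully
    deterministic given ``seed``.
    """
    case_ids = list(case_ids)
    if n_target > len(case_ids):
        raise ValueError(
            f"n_target {n_target} exceeds available cases {len(case_ids)}"
        )
    if chrom_lengths is None:
        chrom_lengths = table.chrom_lengths()
    rng = np.random.default_rng(seed)
    _, full_stats = window_scan(
        table, case_ids, control_ids, chrom_lengths, window_bp, step_bp
    )
    full_top = {
        stat: _top_window_keys(full_stats, stat, quantile)
        for stat in ("fst", "pi_ratio")
    }
    rows = []
    for it in range(iterations):
        chosen = list(rng.choice(case_ids, size=n_target, replace=False))
        _, sub_stats = window_scan(
            table, chosen, control_ids, chrom_lengths, window_bp, step_bp
        )
        row = {"iteration": it}
        for stat in ("fst", "pi_ratio"):
            row[f"rho_{stat}"] = _spearman(
                full_stats[stat].to_numpy(float), sub_stats[stat].to_numpy(float)
            )
            jac, rec = _overlap(
                full_top[stat], _top_window_keys(sub_stats, stat, quantile)
            )
            row[f"jaccard_{stat}"] = jac
            row[f"recall_{stat}"] = rec
        rows.append(row)
    iters = pd.DataFrame(rows)
    metrics = [c for c in iters.columns if c != "iteration"]
    summary = pd.DataFrame(
        {
            "metric": metrics,
            "mean": [iters[m].mean() for m in metrics],
            "p2.5": [iters[m].quantile(0.025) for m in metrics],
            "p97.5": [iters[m].quantile(0.975) for m in metrics],
        }
    )
    return DownsampleReport(
        iterations=iters, summary=summary, n_target=n_target, n_iterations=iterations
    )


# ---------------------------------------------------------------------------
# Block jackknife


_SUM_COLUMNS = ("a", "b", "c", "pi_case", "pi_control")


def _fst_from_sums(sums: pd.Series | pd.DataFrame) -> float | np.ndarray:
    denom = sums["a"] + sums["b"] + sums["c"]
    return np.where(denom > 0, sums["a"] / denom, np.nan) if np.ndim(denom) else (
        sums["a"] / denom if denom > 0 else float("nan")
    )


def block_jackknife(
    components: pd.DataFrame,
    statistic: str | Callable[[pd.DataFrame], float] = "fst",
    block_bp: int = 200_000,
    ci_z: float = 1.96,
) -> JackknifeReport:
    """Delete-one-block jackknife SE and CI for a genome-wide summary.

    ``statistic`` is ``"fst"`` (genome-wide ratio-of-sums Weir-Cockerham),
    ``"pi_ratio"`` (genome-wide sum(pi_control)/sum(pi_case)), or a callable
    evaluated on a components subset.
    """
    if block_bp <= 0:
        raise ValueError("block_bp must be positive")
    valid = ~components[["a", "b", "c"]].isna().any(axis=1)
    comp = components[valid].reset_index(drop=True)
    blocks = (
        comp["chrom"].astype(str)
        + ":"
        + pd.Series((comp["pos"].to_numpy() - 1) // block_bp).astype(str)
    )
    unique_blocks = blocks.unique()
    n_blocks = len(unique_blocks)
    if n_blocks < 2:
        raise ValueError(f"need >= 2 non-empty blocks, got {n_blocks}")

    if callable(statistic):
        name = getattr(statistic, "__name__", "custom")
        estimate = float(statistic(comp))
        deletions = np.array(
            [float(statistic(comp[blocks != b])) for b in unique_blocks]
        )
    else:
        name = statistic
        block_sums = comp[list(_SUM_COLUMNS)].groupby(blocks.to_numpy()).sum()
        totals = comp[list(_SUM_COLUMNS)].sum()
        left_out = totals - block_sums  # per-block delete-one sums
        if statistic == "fst":
            estimate = float(_fst_from_sums(totals))
            denom = left_out["a"] + left_out["b"] + left_out["c"]
            with np.errstate(invalid="ignore", divide="ignore"):
                deletions = np.where(denom > 0, left_out["a"] / denom, np.nan)
        elif statistic == "pi_ratio":
            estimate = float(totals["pi_control"] / totals["pi_case"])
            with np.errstate(invalid="ignore", divide="ignore"):
                deletions = np.where(
                    left_out["pi_case"] > 0,
                    left_out["pi_control"] / left_out["pi_case"],
                    np.nan,
                )
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    deletions = np.asarray(deletions, dtype=float)
    if np.any(np.isnan(deletions)):
        raise ValueError("delete-one estimate undefined for some block")
    center = deletions.mean()
    b = len(deletions)
    se = float(np.sqrt((b - 1) / b * np.sum((deletions - center) ** 2)))
    return JackknifeReport(
        statistic=name,
        estimate=estimate,
        se=se,
        ci_low=estimate - ci_z * se,
        ci_high=estimate + ci_z * se,
        n_blocks=n_blocks,
    )
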