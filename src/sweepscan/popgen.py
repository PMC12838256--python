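"""Weir-Cockerham FST variance components, per-site pi, and window aggregation.

Per biallelic site with two populations (r = 2), let n_i be the number of
called diploids, p_i the alternate-allele frequency and h_i the observed
heterozygote proportion in population i. With

    n_bar = (n_1 + n_2) / r
    n_c   = (r n_bar - sum(n_i^2) / (r n_bar)) / (r - 1)
    p_bar = sum(n_i p_i) / (r n_bar)
    s2    = sum(n_i (p_i - p_bar)^2) / ((r - 1) n_bar)
    h_bar = sum(n_i h_i) / (r n_bar)

the variance components are

    a = (n_bar / n_c) [ s2 - (p_bar(1-p_bar) - s2 (r-1)/r - h_bar/4) / (n_bar - 1) ]
    b = (n_bar / (n_bar - 1)) [ p_bar(1-p_bar) - s2 (r-1)/r - h_bar (2 n_bar - 1)/(4 n_bar) ]
    c = h_bar / 2

a estimates the between-population variance, b the between-individual
within-population variance, and c the within-individual variance; the
windowed FST is the ratio of sums sum(a) / sum(a+b+c), which is the standard
aggregation for windowed Weir-Cockerham scans and is stable at
low-information sites. Negative per-site components are retained in the sums
(no truncation), preserving the estimator's lack of bias.

Per-site nucleotide diversity in a population with m = 2 n_i called allele
copies is the unbiased expected heterozygosity (m/(m-1)) 2 p (1-p), equal to
the mean pairwise difference over all C(m, 2) haplotype pairs at that site.
Window pi is the sum of per-site pi divided by the window span in bp.

Windows are half-open [start, end) 0-based intervals tiled from 0 with a
fixed stride (defaults: 100 kb windows, 50 kb step); with the default 50%
overlap each SNP lands in up to two windows and contributes to both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .containers import MISSING, SiteTable, VariantSite, check_sorted

COMPONENT_COLUMNS = [
    "chrom", "pos", "a", "b", "c",
    "pi_case", "pi_control", "n_case_called", "n_control_called",
]


def _pop_stats(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, alt frequency, het proportion) per site for one population.

    ``gt`` is a (sites x samples) dosage matrix with -1 missing. Frequencies
    are NaN where no calls exist.
    """
    called = gt != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, gt, 0).sum(axis=1).astype(float)
    het = (gt == 1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_components(gt_case: np.ndarray, gt_control: np.ndarray) -> pd.DataFrame:
    """Vectorized per-site components for (sites x samples) dosage matrices.

    Sites with fewer than 2 called diploids in either population get NaN
    components (they are skipped by window aggregation).
    """
    n1, p1, h1 = _pop_stats(np.atleast_2d(gt_case))
    n2, p2, h2 = _pop_stats(np.atleast_2d(gt_control))
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        pi1 = _unbiased_pi(n1, p1)
        pi2 = _unbiased_pi(n2, p2)
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    pi1[n1 < 2] = np.nan
    pi2[n2 < 2] = np.nan
    return pd.DataFrame(
        {
            "a": a,
            "b": b,
            "c": c,
            "pi_case": pi1,
            "pi_control": pi2,
            "n_case_called": n1.astype(int),
            "n_control_called": n2.astype(int),
        }
    )


def _unbiased_pi(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    m = 2.0 * n  # allele copies
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(m > 1, (m / (m - 1.0)) * 2.0 * p * (1.0 - p), np.nan)


def site_components(
    site: VariantSite, case_idx: np.ndarray, control_idx: np.ndarray
) -> pd.Series:
    """Per-site components for one :class:`VariantSite` (see module docs)."""
    frame = wc_components(
        site.genotypes[np.asarray(case_idx)][None, :],
        site.genotypes[np.asarray(control_idx)][None, :],
    )
    row = frame.iloc[0].copy()
    row["chrom"] = site.chrom
    row["pos"] = site.pos
    return row[COMPONENT_COLUMNS]


def theta_per_site(components: pd.DataFrame) -> np.ndarray:
    """Per-site theta = a / (a+b+c); NaN where the denominator is <= 0."""
    denom = (components["a"] + components["b"] + components["c"]).to_numpy()
    a = components["a"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, a / denom, np.nan)


def components_table(
    table: SiteTable, case_ids, control_ids
) -> pd.DataFrame:
    """Per-site components for a whole cohort table, sorted as the table."""
    case_idx = table.sample_indices(case_ids)
    control_idx = table.sample_indices(control_ids)
    frame = wc_components(table.gt[:, case_idx], table.gt[:, control_idx])
    frame.insert(0, "pos", table.pos)
    frame.insert(0, "chrom", table.chrom)
    return frame


def genome_wide_fst(components: pd.DataFrame) -> float:
    """Ratio-of-sums Weir-Cockerham estimate over all informative sites."""
    a = components["a"].to_numpy()
    denom = (components["a"] + components["b"] + components["c"]).to_numpy()
    ok = ~np.isnan(denom)
    total = np.nansum(denom[ok])
    if total <= 0:
        return float("nan")
    return float(np.nansum(a[ok]) / total)


# ---------------------------------------------------------------------------
# Windows


def make_windows(
    chrom_lengths: dict[str, int], window_bp: int = 100_000, step_bp: int = 50_000
) -> pd.DataFrame:
    """Tile half-open [start, end) windows from 0 with the given stride.

    Full windows start at 0, step, 2*step, ... while start + window <= L.
    One final partial window (flagged) is emitted iff it covers at least one
    bp beyond the end of the last full window.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ConfigurationError("window and step sizes must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom} has nonpositive length")
        if length < window_bp:
            rows.append((chrom, 0, length, True))
            continue
        n_full = (length - window_bp) // step_bp + 1
        for k in range(n_full):
            rows.append((chrom, k * step_bp, k * step_bp + window_bp, False))
        last_full_end = (n_full - 1) * step_bp + window_bp
        partial_start = n_full * step_bp
        if partial_start < length and length > last_full_end:
            rows.append((chrom, partial_start, length, True))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def assign_windows(
    chrom: np.ndarray, pos: np.ndarray, windows: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Map each 1-based site to every overlapping window.

    Returns parallel arrays (site_index, window_index); each SNP appears once
    per overlapping window.
    """
    site_idx_parts, win_idx_parts = [], []
    window_index = {
        (row.chrom, row.start): i for i, row in enumerate(windows.itertuples())
    }
    for c in pd.unique(np.asarray(chrom, dtype=object)):
        wsub = windows[windows["chrom"] == c]
        if wsub.empty:
            continue
        starts = wsub["start"].to_numpy()
        ends = wsub["end"].to_numpy()
        site_mask = np.flatnonzero(np.asarray(chrom, dtype=object) == c)
        x = np.asarray(pos)[site_mask] - 1  # 0-based coordinate
        for i, (s, e) in enumerate(zip(starts, ends)):
            hit = site_mask[(x >= s) & (x < e)]
            site_idx_parts.append(hit)
            win_idx_parts.append(
                np.full(len(hit), window_index[(c, int(s))], dtype=np.intp)
            )
    if not site_idx_parts:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    return np.concatenate(site_idx_parts), np.concatenate(win_idx_parts)


def aggregate_windows(
    components: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-site components into per-window statistics.

    Input must be sorted by (chromosome block, position); sites with NaN
    components are skipped. Output columns: chrom, start, end, n_snps, fst,
    pi_case, pi_control, pi_ratio, partial. fst is NaN when the component
    denominator sum is <= 0 or the window holds no informative SNP; pi_ratio
    (= pi_control / pi_case, large values flag case diversity loss) is NaN
    when pi_case is 0 or undefined.
    """
    check_sorted(components["chrom"].to_numpy(), components["pos"].to_numpy())
    valid = ~components[["a", "b", "c"]].isna().any(axis=1)
    comp = components[valid].reset_index(drop=True)
    site_idx, win_idx = assign_windows(
        comp["chrom"].to_numpy(), comp["pos"].to_numpy(), windows
    )
    n_windows = len(windows)
    sums = {}
    for col in ("a", "b", "c", "pi_case", "pi_control"):
        acc = np.zeros(n_windows)
        np.add.at(acc, win_idx, np.nan_to_num(comp[col].to_numpy()[site_idx], nan=0.0))
        sums[col] = acc
    n_snps = np.zeros(n_windows, dtype=int)
    np.add.at(n_snps, win_idx, 1)

    span = (windows["end"] - windows["start"]).to_numpy().astype(float)
    denom = sums["a"] + sums["b"] + sums["c"]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where((n_snps > 0) & (denom > 0), sums["a"] / denom, np.nan)
        pi_case = np.where(n_snps > 0, sums["pi_case"] / span, np.nan)
        pi_control = np.where(n_snps > 0, sums["pi_control"] / span, np.nan)
        pi_ratio = np.where(
            (n_snps > 0) & (pi_case > 0), pi_control / pi_case, np.nan
        )
    out = windows[["chrom", "start", "end"]].copy()
    out["n_snps"] = n_snps
    out["fst"] = fst
    out["pi_case"] = pi_case
    out["pi_control"] = pi_control
    out["pi_ratio"] = pi_ratio
    out["partial"] = windows["partial"].to_numpy()
    return out


def window_scan(
    table: SiteTable,
    case_ids,
    control_ids,
    chrom_lengths: dict[str, int] | None = None,
    window_bp: int = 100_000,
    step_bp: int = 50_000,
    invert_pi_ratio: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full windowed scan: components plus per-window FST and pi-ratio.

    ``invert_pi_ratio`` switches the reported ratio to pi_case/pi_control;
    outlier calling then ranks the lower tail equivalently, so the default
    (control/case, upper tail) is used throughout the pipeline.
    """
    if chrom_lengths is None:
        chrom_lengths = table.chrom_lengths()
    comp = components_table(table, case_ids, control_ids)
    windows = make_windows(chrom_lengths, window_bp=window_bp, step_bp=step_bp)
    stats = aggregate_windows(comp, windows)
    if invert_pi_ratio:
        with np.errstate(invalid="ignore", divide="ignore"):
            inverted = np.where(
                stats["pi_control"] > 0, stats["pi_case"] / stats["pi_control"], np.nan
            )
        stats["pi_ratio"] = np.where(stats["n_snps"] > 0, inverted, np.nan)
    return comp, stats
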