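"""Hard site filters, genotype-level masking, and the biallelic retention rule.

Filter order is fixed: site hard filters -> genotype masking -> biallelic
rule. All inequalities are strict exactly as printed in GATK-style filter
expressions, so boundary values (QD = 3.0, GQ = 20, DP = 3x mean, AD ratio
= 0.2) pass. A missing site annotation means the corresponding rule is
skipped for that site (GATK emits several annotations conditionally); this is
logged once per key, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, SiteTable, VariantSite

logger = logging.getLogger("sweepscan.filters")

#: SNP site rules: INFO key -> (comparison, threshold); "lt" fails when
#: value < threshold, "gt" fails when value > threshold.
SNP_SITE_RULES: dict[str, tuple[str, float]] = {
    "QD": ("lt", 3.0),
    "FS": ("gt", 30.0),
    "SOR": ("gt", 4.0),
    "MQ": ("lt", 30.0),
    "MQRankSum": ("lt", -10.0),
    "QUAL": ("lt", 50.0),
    "RPRS": ("lt", -5.0),  # ReadPosRankSum
}

#: InDel rules, behind a variant-type switch (the sweep scan itself is
#: SNP-only).
INDEL_SITE_RULES: dict[str, tuple[str, float]] = {
    "QD": ("lt", 3.0),
    "FS": ("gt", 100.0),
    "RPRS": ("lt", -10.0),
}


@dataclass
class FilterThresholds:
    """Site- and genotype-level filter thresholds.

    Genotype rules: GQ < ``gq_min`` masks the call; DP outside
    (mean/``dp_low_divisor``, ``dp_high_factor`` x mean) of the individual's
    own mean depth masks it; a heterozygote whose minor allele depth fraction
    min(AD)/sum(AD) < ``ad_ratio_min`` masks it.
    """

    site_rules: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(SNP_SITE_RULES)
    )
    gq_min: float = 20.0
    dp_low_divisor: float = 3.0
    dp_high_factor: float = 3.0
    ad_ratio_min: float = 0.2

    @classmethod
    def for_indels(cls) -> "FilterThresholds":
        return cls(site_rules=dict(INDEL_SITE_RULES))


_warned_missing_keys: set[str] = set()


def _rule_fails(value: float, op: str, threshold: float) -> bool:
    if op == "lt":
        return value < threshold
    if op == "gt":
        return value > threshold
    raise ValueError(f"unknown comparison {op!r}")


def filter_site(
    site: VariantSite, thresholds: FilterThresholds | None = None
) -> tuple[bool, list[str]]:
    """Evaluate hard site filters; returns (passed, failure reasons).

    A site fails iff ANY rule's inequality holds (OR semantics). Every
    violated rule is reported.
    """
    thresholds = thresholds or FilterThresholds()
    reasons = []
    for key, (op, cutoff) in thresholds.site_rules.items():
        value = site.info.get(key)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if key not in _warned_missing_keys:
                logger.warning("INFO key %s absent; rule skipped where missing", key)
                _warned_missing_keys.add(key)
            continue
        if _rule_fails(float(value), op, cutoff):
            symbol = "<" if op == "lt" else ">"
            reasons.append(f"{key} {symbol} {cutoff}")
    return (len(reasons) == 0, reasons)


def filter_genotypes(
    site: VariantSite,
    per_individual_mean_depth: np.ndarray,
    thresholds: FilterThresholds | None = None,
) -> VariantSite:
    """Mask genotypes violating the GQ / DP / heterozygote-AD rules.

    ``per_individual_mean_depth`` is each sample's mean whole-genome depth,
    in the site's sample order. Masked calls become missing; all other fields
    are untouched.
    """
    thresholds = thresholds or FilterThresholds()
    mean_depth = np.asarray(per_individual_mean_depth, dtype=float)
    if len(mean_depth) != site.n_samples:
        raise ValueError("mean depth required for every sample")
    if np.any(mean_depth <= 0):
        raise ValueError("per-individual mean depth must be positive")
    out = site.copy()
    mask = np.zeros(site.n_samples, dtype=bool)
    if site.gq is not None:
        known = site.gq != MISSING
        mask |= known & (site.gq < thresholds.gq_min)
    if site.dp is not None:
        known = site.dp != MISSING
        low = mean_depth / thresholds.dp_low_divisor
        high = mean_depth * thresholds.dp_high_factor
        mask |= known & ((site.dp < low) | (site.dp > high))
    if site.ad is not None:
        het = site.genotypes == 1
        known = (site.ad[:, 0] != MISSING) & (site.ad[:, 1] != MISSING)
        total = site.ad.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, site.ad.min(axis=1) / total, 0.0)
        mask |= het & known & (ratio < thresholds.ad_ratio_min)
    out.genotypes = np.where(mask, MISSING, site.genotypes).astype(np.int8)
    return out


def apply_biallelic_rule(site: VariantSite) -> tuple[bool, str]:
    """Keep a (masked) site iff 0 < alt allele frequency < 1.

    Returns (keep, reason); reason is empty when kept.
    """
    called = site.genotypes != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return False, "all-missing"
    alt_count = int(site.genotypes[called].sum())
    if alt_count == 0:
        return False, "AC=0"
    if alt_count == 2 * n_called:
        return False, "AF=1"
    return True, ""


# ---------------------------------------------------------------------------
# Vectorized pipeline over SiteTable


def mean_depth_per_sample(table: SiteTable) -> np.ndarray:
    """Each individual's mean depth over all sites with known DP."""
    if table.dp is None:
        raise ValueError("table carries no DP")
    dp = np.where(table.dp == MISSING, np.nan, table.dp.astype(float))
    return np.nanmean(dp, axis=0)


def filter_table(
    table: SiteTable,
    per_individual_mean_depth: np.ndarray | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[SiteTable, pd.DataFrame]:
    """Run the full filter cascade on a columnar table.

    Returns the surviving table (with masked genotypes) and a summary frame
    (rule -> sites or genotypes removed). Equivalent to streaming each site
    through :func:`filter_site`, :func:`filter_genotypes` and
    :func:`apply_biallelic_rule`; the per-site functions are the reference
    semantics.
    """
    thresholds = thresholds or FilterThresholds()
    summary_rows: list[tuple[str, int]] = []

    # --- site hard filters
    site_fail = np.zeros(table.n_sites, dtype=bool)
    if table.info is not None:
        for key, (op, cutoff) in thresholds.site_rules.items():
            if key not in table.info.columns:
                continue
            values = table.info[key].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                fails = (values < cutoff) if op == "lt" else (values > cutoff)
            fails &= ~np.isnan(values)
            symbol = "<" if op == "lt" else ">"
            summary_rows.append((f"site {key} {symbol} {cutoff}", int(fails.sum())))
            site_fail |= fails
    summary_rows.append(("sites failing hard filters", int(site_fail.sum())))
    kept = table.take_sites(~site_fail)

    # --- genotype masking
    if per_individual_mean_depth is None:
        per_individual_mean_depth = mean_depth_per_sample(table)
    mean_depth = np.asarray(per_individual_mean_depth, dtype=float)
    if np.any(mean_depth <= 0):
        raise ValueError("per-individual mean depth must be positive")
    mask = np.zeros(kept.gt.shape, dtype=bool)
    if kept.gq is not None:
        mask |= (kept.gq != MISSING) & (kept.gq < thresholds.gq_min)
    if kept.dp is not None:
        low = mean_depth / thresholds.dp_low_divisor
        high = mean_depth * thresholds.dp_high_factor
        known = kept.dp != MISSING
        mask |= known & ((kept.dp < low[None, :]) | (kept.dp > high[None, :]))
    if kept.ad_alt is not None and kept.ad_ref is not None:
        het = kept.gt == 1
        known = (kept.ad_alt != MISSING) & (kept.ad_ref != MISSING)
        alt = kept.ad_alt.astype(float)
        ref = kept.ad_ref.astype(float)
        total = alt + ref
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, np.minimum(alt, ref) / total, 0.0)
        mask |= het & known & (ratio < thresholds.ad_ratio_min)
    summary_rows.append(("genotypes masked", int((mask & (kept.gt != MISSING)).sum())))
    kept.gt = np.where(mask, MISSING, kept.gt).astype(np.int8)

    # --- biallelic rule on masked genotypes
    called = kept.gt != MISSING
    n_called = called.sum(axis=1)
    alt_count = np.where(called, kept.gt, 0).sum(axis=1)
    keep = (n_called > 0) & (alt_count > 0) & (alt_count < 2 * n_called)
    summary_rows.append(("sites dropped by biallelic rule", int((~keep).sum())))
    result = kept.take_sites(keep)
    summary_rows.append(("sites retained", result.n_sites))
    summary = pd.DataFrame(summary_rows, columns=["rule", "count"])
    return result, summary
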