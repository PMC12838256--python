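"""Phenotype group comparison: trait summaries and two-sample t-tests.

Case vs. control cranial measurements are compared with Welch's unequal-
variance t-test (two-sided, Welch-Satterthwaite degrees of freedom) — the
defensible default for a 145/30 group imbalance; a pooled-variance mode is
available behind a flag. A summary-statistics path reproduces the test from
printed group means/SDs without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TraitSummary:
    trait: str
    case_mean: float
    case_sd: float
    case_n: int
    control_mean: float
    control_sd: float
    control_n: int
    mean_difference: float  # case - control
    t: float
    df: float
    p: float

    def as_row(self) -> dict:
        return vars(self).copy()


def test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    trait: str = "trait",
    pooled: bool = False,
) -> TraitSummary:
    """Two-sample t-test from group summary statistics (group1 - group2).

    Zero-variance degenerate input is handled by convention: equal means give
    t = 0, p = 1; unequal means with zero variance are an error.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    diff = mean1 - mean2
    if sd1 == 0 and sd2 == 0:
        if diff == 0:
            t, df, p = 0.0, float(n1 + n2 - 2), 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        t, p = sps.ttest_ind_from_stats(
            mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled
        )
        t, p = float(t), float(p)
        df = _degrees_of_freedom(sd1, n1, sd2, n2, pooled)
    return TraitSummary(
        trait=trait,
        case_mean=mean1,
        case_sd=sd1,
        case_n=n1,
        control_mean=mean2,
        control_sd=sd2,
        control_n=n2,
        mean_difference=diff,
        t=t,
        df=df,
        p=p,
    )


def _degrees_of_freedom(sd1: float, n1: int, sd2: float, n2: int, pooled: bool) -> float:
    if pooled:
        return float(n1 + n2 - 2)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        return float(n1 + n2 - 2)
    return float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))


def summarize_and_test(
    table: pd.DataFrame,
    group_column: str = "group",
    case_label: str = "case",
    control_label: str = "control",
    traits: list[str] | None = None,
    pooled: bool = False,
) -> list[TraitSummary]:
    """Per-trait group summaries and t-tests from a raw phenotype table.

    Group SDs use the n-1 denominator; the mean difference is case - control.
    Traits default to every numeric column apart from the group label.
    """
    if traits is None:
        traits = [
            c
            for c in table.columns
            if c != group_column and pd.api.types.is_numeric_dtype(table[c])
        ]
    case = table[table[group_column] == case_label]
    control = table[table[group_column] == control_label]
    results = []
    for trait in traits:
        x = case[trait].dropna().to_numpy(dtype=float)
        y = control[trait].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"trait {trait}: each group needs >= 2 values")
        results.append(
            test_from_summary(
                float(np.mean(x)),
                float(np.std(x, ddof=1)),
                len(x),
                float(np.mean(y)),
                float(np.std(y, ddof=1)),
                len(y),
                trait=trait,
                pooled=pooled,
            )
        )
    return results


def summaries_frame(summaries: list[TraitSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])
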