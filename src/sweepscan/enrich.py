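"""Over-representation analysis on a user-supplied gene-to-term map.

For each annotation term, with N universe genes, K of them carrying the
term, n candidate genes and k candidates carrying the term, the upper-tail
hypergeometric probability P(X >= k) tests whether the term is carried more
often than chance among candidates. p-values are Benjamini-Hochberg adjusted
across all tested terms; terms with zero candidate overlap are excluded from
the family before adjustment (the usual over-representation convention —
this choice affects adjusted p and is therefore stated here). Terms with
adjusted p below the significance level (default 0.05) are flagged.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["term_id", "k", "K", "n", "N", "p", "p_adjusted", "significant"]


def _term_to_genes(term_map: pd.DataFrame | Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    if isinstance(term_map, pd.DataFrame):
        out: dict[str, set[str]] = {}
        for gene, term in term_map[["gene_id", "term_id"]].itertuples(index=False):
            out.setdefault(str(term), set()).add(str(gene))
        return out
    return {term: set(genes) for term, genes in term_map.items()}


def overrepresentation(
    candidates: Iterable[str],
    term_map: pd.DataFrame | Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms among candidate genes.

    Parameters
    ----------
    candidates : candidate gene IDs; must all belong to ``universe``
    term_map : DataFrame with columns gene_id/term_id, or term -> genes map
    universe : background gene set (typically all annotated genes)
    alpha : adjusted-p significance cutoff

    Returns a DataFrame (one row per term with >= 1 candidate gene) sorted by
    p, with raw and BH-adjusted p-values and a significance flag.
    """
    universe = set(map(str, universe))
    candidates = set(map(str, candidates))
    stray = sorted(candidates - universe)
    if stray:
        raise ValueError(f"candidate genes absent from universe: {stray}")
    terms = _term_to_genes(term_map)
    n = len(candidates)
    big_n = len(universe)
    rows = []
    for term, genes in terms.items():
        genes_in_universe = genes & universe
        big_k = len(genes_in_universe)
        if big_k == 0:
            continue
        k = len(genes_in_universe & candidates)
        if k == 0:
            continue  # excluded from the BH family
        p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, k, big_k, n, big_n, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    reject, p_adj, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    out["p_adjusted"] = p_adj
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values(["p", "term_id"], ignore_index=True)
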