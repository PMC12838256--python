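"""Independent reference implementations used only to check the package.

Everything here is written as a direct, scalar, step-by-step transcription of
the defining formulas (or as brute-force enumeration), deliberately sharing
no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math


def wc_components_oracle(case_gts: list[int], control_gts: list[int]):
    """Weir-Cockerham variance components for two populations, scalar.

    Genotypes are alt-allele dosages (0/1/2); missing calls are simply not
    included in the lists. Returns (a, b, c) or None when either population
    has fewer than two called diploids.
    """
    r = 2
    pops = [case_gts, control_gts]
    n = [len(g) for g in pops]
    if min(n) < 2:
        return None
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]

    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def pi_bruteforce(genotypes: list[int]) -> float:
    """Mean pairwise difference over all haplotype pairs at one site.

    Expands diploid dosages into a haplotype multiset (0/1 alleles) and
    averages the indicator of difference over all C(m, 2) pairs.
    """
    haplotypes: list[int] = []
    for g in genotypes:
        if g == 0:
            haplotypes += [0, 0]
        elif g == 1:
            haplotypes += [0, 1]
        elif g == 2:
            haplotypes += [1, 1]
        else:
            raise ValueError(f"bad dosage {g}")
    pairs = list(itertools.combinations(haplotypes, 2))
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def hypergeom_tail_oracle(big_n: int, big_k: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all n-subsets of the universe.

    Feasible for universes of a dozen genes; genes 0..K-1 carry the term.
    """
    total = 0
    hits = 0
    for subset in itertools.combinations(range(big_n), n):
        total += 1
        if sum(1 for g in subset if g < big_k) >= k:
            hits += 1
    return hits / total


def welch_t_oracle(mean1, sd1, n1, mean2, sd2, n2):
    """Welch t statistic and Welch-Satterthwaite df, from first principles."""
    se2 = sd1**2 / n1 + sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    return t, df


def genes_near_snps_bruteforce(snps, genes, flank_bp):
    """All-pairs SNP-to-gene distance scan; returns {gene_id: n_supporting}."""
    out: dict[str, int] = {}
    for gene in genes:
        count = 0
        for chrom, pos in snps:
            if chrom != gene.chrom:
                continue
            if pos < gene.start:
                dist = gene.start - pos
            elif pos > gene.end:
                dist = pos - gene.end
            else:
                dist = 0
            if dist <= flank_bp:
                count += 1
        if count:
            out[gene.gene_id] = count
    return out
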