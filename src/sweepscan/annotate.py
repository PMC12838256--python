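"""Candidate-gene assignment: genes within ±50 kb of selected SNPs.

A gene is a candidate iff some selected SNP on the same chromosome lies
within ``flank_bp`` of the gene interval — distance 0 inside the interval,
otherwise bp distance to the nearer boundary, compared inclusively
(distance <= flank_bp). Gene midpoints are never used; strand is ignored.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .containers import GeneRecord


def genes_near_snps(
    selected_snps: pd.DataFrame,
    genes: Sequence[GeneRecord],
    flank_bp: int = 50_000,
    chromosome_allowlist: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Genes within ``flank_bp`` of any selected SNP, with supporting counts.

    Parameters
    ----------
    selected_snps : DataFrame with columns chrom, pos (1-based)
    genes : gene intervals (1-based inclusive)
    flank_bp : maximum SNP-to-interval distance, inclusive
    chromosome_allowlist : optional restriction (e.g. autosomes only); SNPs
        and genes outside it are dropped before matching

    Returns a DataFrame (gene_id, chrom, start, end, n_supporting_snps)
    sorted by position. Raises when selected SNPs sit on chromosomes absent
    from the gene annotation.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    snps = selected_snps
    if chromosome_allowlist is not None:
        allowed = set(chromosome_allowlist)
        snps = snps[snps["chrom"].isin(allowed)]
        genes = [g for g in genes if g.chrom in allowed]
    gene_chroms = {g.chrom for g in genes}
    snp_chroms = set(snps["chrom"].unique())
    unmatched = sorted(snp_chroms - gene_chroms)
    if unmatched:
        raise ValueError(
            f"selected SNPs on chromosomes without gene annotation: {unmatched}"
        )

    # interval tree over flank-expanded gene intervals, 1-based inclusive
    # intervals stored half-open [start, end+1)
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        tree.addi(gene.start - flank_bp, gene.end + flank_bp + 1, gene)

    counts: dict[str, int] = {}
    records: dict[str, GeneRecord] = {}
    for chrom, group in snps.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos in group["pos"].to_numpy():
            for hit in tree.at(int(pos)):
                gene = hit.data
                counts[gene.gene_id] = counts.get(gene.gene_id, 0) + 1
                records[gene.gene_id] = gene
    rows = [
        (g.gene_id, g.chrom, g.start, g.end, counts[g.gene_id])
        for g in records.values()
    ]
    out = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "n_supporting_snps"]
    )
    return out.sort_values(["chrom", "start", "gene_id"], ignore_index=True)


def snp_gene_distance(pos: int, gene: GeneRecord) -> int:
    """bp distance between a SNP and a gene interval (0 inside)."""
    if pos < gene.start:
        return gene.start - pos
    if pos > gene.end:
        return pos - gene.end
    return 0
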