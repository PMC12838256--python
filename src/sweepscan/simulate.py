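"""Synthetic two-population cohort generator.

Emulates a case/control whole-genome resequencing experiment so the full
sweep-scan pipeline is testable without the deposited raw data:

* Per SNP, an ancestral allele frequency ``p ~ Uniform(0.05, 0.95)``.
* Population frequencies follow the Balding-Nichols model,
  ``p_pop ~ Beta(p (1-F)/F, (1-p)(1-F)/F)``, with ``F = background_fst``
  outside sweep regions and ``F = sweep_fst`` inside them. Balding-Nichols is
  used because its F parameter *is* the expected FST, giving an analytically
  known truth for parameter-recovery checks.
* Inside a sweep region the case frequency is additionally pushed toward
  fixation so that case expected heterozygosity is multiplied by the region's
  ``case_diversity_factor`` — the sweep therefore lifts both scan statistics
  (FST and the control/case pi-ratio) at once.
* Diploid genotypes are Binomial(2, p_pop) draws; read depth is
  Poisson(mean_depth), allele depths split Binomial(DP, dosage/2), and GQ is
  high (>= 30) apart from a configurable corrupted fraction (< 20). Site INFO
  annotations (QD/FS/SOR/MQ/MQRankSum/QUAL/ReadPosRankSum) carry passing
  values apart from a configurable corrupted fraction, so the hard filters
  have something to remove.

Monomorphic draws (both populations fixed) are retained in the output; the
downstream biallelic AC>0 / AF<1 rule is expected to drop them.

All output is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    PhenotypeConfig,
    SimulationConfig,
    dump_simulation_config,
)
from .containers import INFO_KEYS, SiteTable

_PASSING_INFO = {
    "QD": (15.0, 35.0),
    "FS": (0.0, 5.0),
    "SOR": (0.5, 2.5),
    "MQ": (55.0, 60.0),
    "QUAL": (200.0, 1000.0),
}
_FAILING_INFO = {
    "QD": (0.0, 2.9),
    "FS": (31.0, 200.0),
    "SOR": (4.1, 9.0),
    "MQ": (5.0, 29.9),
    "MQRankSum": (-20.0, -10.1),
    "QUAL": (0.0, 49.0),
    "RPRS": (-20.0, -5.1),
}


def case_ids(n: int) -> list[str]:
    return [f"case_{i + 1:03d}" for i in range(n)]


def control_ids(n: int) -> list[str]:
    return [f"ctrl_{i + 1:03d}" for i in range(n)]


def _shrink_toward_fixation(p: np.ndarray, factor: np.ndarray) -> np.ndarray:
    """Move frequencies toward 0 or 1 so 2p(1-p) is scaled by ``factor``.

    Solves 2p'(1-p') = factor * 2p(1-p) on the side of 1/2 where p already
    lies, i.e. toward fixation of the locally common allele.
    """
    target_het = factor * 2.0 * p * (1.0 - p)  # <= 1/2 always
    root = np.sqrt(np.clip(1.0 - 2.0 * target_het, 0.0, None))
    low = 0.5 * (1.0 - root)
    high = 0.5 * (1.0 + root)
    return np.where(p <= 0.5, low, high)


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: np.ndarray
) -> np.ndarray:
    """Population frequency draw; F = 0 degenerates to the ancestral p."""
    out = p.copy()
    active = fst > 0
    if np.any(active):
        scale = (1.0 - fst[active]) / fst[active]
        out[active] = rng.beta(p[active] * scale, (1.0 - p[active]) * scale)
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[SiteTable, dict]:
    """Generate the cohort genotype table and the sample manifest.

    Returns
    -------
    table : SiteTable
        All simulated SNPs (including monomorphic draws) with genotype-level
        DP/GQ/AD and site-level INFO annotations.
    manifest : dict
        ``{"case_ids": [...], "control_ids": [...]}``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cases = case_ids(config.n_case)
    controls = control_ids(config.n_control)
    samples = cases + controls

    chroms, positions = [], []
    for chrom in config.chrom_names:
        n = rng.poisson(config.snp_density * config.chrom_length_bp)
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=n))
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n_sites = len(pos)

    # per-site differentiation parameter and sweep membership
    fst = np.full(n_sites, config.background_fst)
    diversity_factor = np.ones(n_sites)
    for region in config.sweep_regions:
        inside = (chrom == region.chrom) & (pos >= region.start_bp) & (pos <= region.end_bp)
        fst[inside] = region.sweep_fst
        diversity_factor[inside] = region.case_diversity_factor

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    p_case = _balding_nichols(rng, p_anc, fst)
    p_control = _balding_nichols(rng, p_anc, fst)
    shrink = diversity_factor < 1.0
    p_case[shrink] = _shrink_toward_fixation(p_case[shrink], diversity_factor[shrink])

    gt = np.empty((n_sites, len(samples)), dtype=np.int8)
    gt[:, : config.n_case] = rng.binomial(
        2, p_case[:, None], size=(n_sites, config.n_case)
    )
    gt[:, config.n_case :] = rng.binomial(
        2, p_control[:, None], size=(n_sites, config.n_control)
    )

    dp = rng.poisson(config.mean_depth, size=gt.shape).astype(np.int32)
    ad_alt = rng.binomial(dp, gt / 2.0).astype(np.int32)
    gq = rng.integers(30, 100, size=gt.shape).astype(np.int32)
    bad_gq = rng.random(gt.shape) < config.corrupt_gq_fraction
    gq[bad_gq] = rng.integers(0, 20, size=int(bad_gq.sum()))

    info = pd.DataFrame(index=np.arange(n_sites), columns=list(INFO_KEYS), dtype=float)
    for key, (lo, hi) in _PASSING_INFO.items():
        info[key] = rng.uniform(lo, hi, size=n_sites)
    info["MQRankSum"] = np.clip(rng.normal(0.0, 1.0, size=n_sites), -9.9, None)
    info["RPRS"] = np.clip(rng.normal(0.0, 1.0, size=n_sites), -4.9, None)
    bad_sites = np.flatnonzero(rng.random(n_sites) < config.corrupt_info_fraction)
    fail_keys = list(_FAILING_INFO)
    which = rng.integers(0, len(fail_keys), size=len(bad_sites))
    for j, key in enumerate(fail_keys):
        rows = bad_sites[which == j]
        lo, hi = _FAILING_INFO[key]
        info.loc[rows, key] = rng.uniform(lo, hi, size=len(rows))
    # round to 3 decimals and pass through float32 so values survive a VCF
    # write -> htslib read cycle bit-exactly
    info = info.round(3).astype(np.float32).astype(np.float64)

    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "T", dtype=object)
    table = SiteTable(
        samples, chrom, pos, ref, alt, gt,
        dp=dp, gq=gq, ad_ref=dp - ad_alt, ad_alt=ad_alt, info=info,
    )
    return table, {"case_ids": cases, "control_ids": controls}


def simulate_phenotypes(
    pconfig: PhenotypeConfig, n_case: int, n_control: int, seed: int
) -> pd.DataFrame:
    """Draw per-individual trait values from the group Normal distributions."""
    pconfig.validate()
    if n_case < 1 or n_control < 1:
        raise ConfigurationError("need at least one individual per group")
    rng = np.random.default_rng(seed)
    rows = {
        "individual_id": case_ids(n_case) + control_ids(n_control),
        "group": ["case"] * n_case + ["control"] * n_control,
    }
    table = pd.DataFrame(rows)
    for trait, (case_mean, case_sd, ctrl_mean, ctrl_sd) in pconfig.traits.items():
        values = np.empty(n_case + n_control)
        values[:n_case] = rng.normal(case_mean, case_sd, size=n_case)
        values[n_case:] = rng.normal(ctrl_mean, ctrl_sd, size=n_control)
        table[trait] = values
    return table


def tile_genes(
    config: SimulationConfig,
    gene_length_bp: int = 20_000,
    spacing_bp: int = 120_000,
    first_start_bp: int = 10_001,
) -> list:
    """Lay toy genes on a regular grid along every chromosome.

    The default grid guarantees, for each default-sized sweep region, genes
    inside it, genes within 50 kb of it, and genes far beyond 50 kb.
    """
    from .containers import GeneRecord

    genes = []
    for chrom in config.chrom_names:
        k = 0
        start = first_start_bp
        while start + gene_length_bp - 1 <= config.chrom_length_bp:
            genes.append(
                GeneRecord(f"{chrom}_gene{k:03d}", chrom, start, start + gene_length_bp - 1)
            )
            k += 1
            start += spacing_bp
    return genes


def _interval_distance(pos_start: int, pos_end: int, start: int, end: int) -> int:
    if pos_end < start:
        return start - pos_end
    if end < pos_start:
        return pos_start - end
    return 0


def sweep_adjacent_genes(
    config: SimulationConfig, genes, flank_bp: int = 50_000
) -> set[str]:
    """Gene IDs within ``flank_bp`` of any sweep region interval."""
    hits = set()
    for gene in genes:
        for region in config.sweep_regions:
            if gene.chrom != region.chrom:
                continue
            if _interval_distance(gene.start, gene.end, region.start_bp, region.end_bp) <= flank_bp:
                hits.add(gene.gene_id)
    return hits


def make_term_map(
    config: SimulationConfig, genes, n_background_terms: int = 5
) -> pd.DataFrame:
    """Gene-to-term map with one term enriched among sweep-region genes.

    Every gene gets a round-robin background term; genes within 50 kb of a
    sweep region additionally carry ``T_sweep``.
    """
    sweep_genes = sweep_adjacent_genes(config, genes)
    rows = []
    for i, gene in enumerate(genes):
        rows.append((gene.gene_id, f"T_bg{i % n_background_terms + 1}"))
        if gene.gene_id in sweep_genes:
            rows.append((gene.gene_id, "T_sweep"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def write_fixture_bundle(
    config: SimulationConfig, pconfig: PhenotypeConfig, outdir: str
) -> dict[str, str]:
    """Write the full synthetic input set for one pipeline run.

    Produces cohort VCF, toy GFF3 annotation, case/control sample lists,
    phenotype TSV, gene-to-term map, and the YAML config used. Returns a
    name -> path mapping.
    """
    from . import io as sio

    os.makedirs(outdir, exist_ok=True)
    table, manifest = simulate_cohort(config)
    genes = tile_genes(config)
    phenotypes = simulate_phenotypes(
        pconfig, config.n_case, config.n_control, seed=config.seed + 1
    )
    term_map = make_term_map(config, genes)

    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "cases": os.path.join(outdir, "cases.txt"),
        "controls": os.path.join(outdir, "controls.txt"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "term_map": os.path.join(outdir, "gene2term.tsv"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    try:
        sio.write_vcf(table, paths["vcf"], chrom_lengths=config.chrom_lengths)
        sio.write_gff_genes(genes, paths["gff"])
        sio.write_sample_list(manifest["case_ids"], paths["cases"])
        sio.write_sample_list(manifest["control_ids"], paths["controls"])
        phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
        term_map.to_csv(paths["term_map"], sep="\t", index=False)
        dump_simulation_config(config, paths["config"])
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {outdir}: {exc}") from exc
    return paths
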