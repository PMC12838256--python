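"""Synthetic cohort generator: determinism, parameter recovery, phenotypes."""

import numpy as np
import pytest

from sweepscan import (
    ConfigurationError,
    PhenotypeConfig,
    SimulationConfig,
    SweepRegionSpec,
    components_table,
    genome_wide_fst,
    simulate_cohort,
    simulate_phenotypes,
    write_fixture_bundle,
)
from sweepscan.popgen import theta_per_site
from sweepscan.simulate import sweep_adjacent_genes, tile_genes


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_case": 1},
            {"n_control": 1},
            {"background_fst": -0.1},
            {"background_fst": 1.0},
            {"snp_density": 0.0},
            {"mean_depth": 0.0},
            {"sweep_regions": [("chr9", 1, 100, 0.5, 0.3)]},  # unknown chrom
            {"sweep_regions": [("chr1", 0, 100, 0.5, 0.3)]},  # out of bounds
            {"sweep_regions": [("chr1", 1, 100, 0.01, 0.3)]},  # below background
            {"sweep_regions": [("chr1", 1, 100, 0.5, 0.0)]},  # bad diversity factor
            {
                "sweep_regions": [
                    ("chr1", 1, 200_000, 0.5, 0.3),
                    ("chr1", 100_000, 300_000, 0.5, 0.3),
                ]
            },  # overlapping sweeps
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_defaults_are_valid(self):
        config = SimulationConfig()
        assert config.n_case == 145 and config.n_control == 30


class TestCohortSimulation:
    def test_deterministic_given_seed(self, tmp_path):
        config = SimulationConfig(seed=5, snp_density=0.0003)
        a = write_fixture_bundle(config, PhenotypeConfig(), str(tmp_path / "a"))
        b = write_fixture_bundle(config, PhenotypeConfig(), str(tmp_path / "b"))
        assert open(a["vcf"]).read() == open(b["vcf"]).read()
        assert open(a["phenotypes"]).read() == open(b["phenotypes"]).read()

    def test_zero_background_fst_means_no_differentiation(self):
        config = SimulationConfig(
            seed=3, background_fst=0.0, sweep_regions=[], snp_density=0.003,
            n_case=40, n_control=40,
        )
        table, manifest = simulate_cohort(config)
        comp = components_table(table, manifest["case_ids"], manifest["control_ids"])
        theta = theta_per_site(comp)
        assert abs(np.nanmean(theta)) < 0.01

    def test_background_fst_recovered_by_ratio_of_sums(self):
        """Genome-wide Weir-Cockerham estimate converges to the Balding-Nichols F."""
        config = SimulationConfig(
            seed=4, background_fst=0.05, sweep_regions=[], snp_density=0.01
        )
        table, manifest = simulate_cohort(config)
        assert table.n_sites >= 50_000
        comp = components_table(table, manifest["case_ids"], manifest["control_ids"])
        assert genome_wide_fst(comp) == pytest.approx(0.05, abs=0.01)

    def test_case_diversity_shrinks_by_configured_factor(self):
        """Mean case pi inside the sweep ~ factor x neutral case pi."""
        factor = 0.3
        config = SimulationConfig(
            seed=6,
            n_chromosomes=1,
            chrom_length_bp=4_000_000,
            snp_density=0.01,
            background_fst=0.02,
            sweep_regions=[SweepRegionSpec("chr1", 1, 2_000_000, 0.021, factor)],
        )
        table, manifest = simulate_cohort(config)
        comp = components_table(table, manifest["case_ids"], manifest["control_ids"])
        inside = comp["pos"] <= 2_000_000
        ratio = comp.loc[inside, "pi_case"].mean() / comp.loc[~inside, "pi_case"].mean()
        assert ratio == pytest.approx(factor, abs=0.05)

    def test_sample_count_and_manifest(self):
        config = SimulationConfig(seed=1, snp_density=0.0002)
        table, manifest = simulate_cohort(config)
        assert table.n_samples == 175
        assert len(manifest["case_ids"]) == 145
        assert len(manifest["control_ids"]) == 30

    def test_monomorphic_draws_retained_until_biallelic_rule(self):
        from sweepscan import filter_table

        config = SimulationConfig(
            seed=8, snp_density=0.002, n_case=5, n_control=5,
            corrupt_gq_fraction=0.0, corrupt_info_fraction=0.0,
        )
        table, _ = simulate_cohort(config)
        called_alt = table.gt.sum(axis=1)
        mono = (called_alt == 0) | (called_alt == 2 * table.n_samples)
        assert mono.any()  # generator keeps them ...
        filtered, _ = filter_table(table)
        alt = filtered.gt.clip(0).sum(axis=1)  # ... the filter removes them
        n_called = (filtered.gt >= 0).sum(axis=1)
        assert ((alt > 0) & (alt < 2 * n_called)).all()


class TestPhenotypes:
    def test_large_sample_recovers_group_means(self):
        table = simulate_phenotypes(PhenotypeConfig(), 10_000, 10_000, seed=0)
        case = table[table["group"] == "case"]
        control = table[table["group"] == "control"]
        assert case["maxillary_length_mm"].mean() == pytest.approx(149.12, abs=1.0)
        assert control["maxillary_length_mm"].mean() == pytest.approx(156.92, abs=1.0)
        assert case["mandible_length_mm"].mean() == pytest.approx(197.43, abs=1.5)

    def test_tiny_sd_degenerates_to_group_mean(self):
        pconfig = PhenotypeConfig(
            traits={"maxillary_length_mm": (149.12, 1e-9, 156.92, 1e-9)}
        )
        table = simulate_phenotypes(pconfig, 5, 5, seed=0)
        case = table[table["group"] == "case"]["maxillary_length_mm"]
        assert np.allclose(case, 149.12)

    def test_deterministic_given_seed(self):
        a = simulate_phenotypes(PhenotypeConfig(), 20, 10, seed=9)
        b = simulate_phenotypes(PhenotypeConfig(), 20, 10, seed=9)
        assert a.equals(b)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            PhenotypeConfig(traits={"t": (1.0, 0.0, 1.0, 1.0)})


class TestFixtureLayout:
    def test_gene_grid_covers_all_distance_classes(self):
        """Genes inside, within 50 kb of, and far from the sweep all exist."""
        config = SimulationConfig(seed=0)
        genes = tile_genes(config)
        region = config.sweep_regions[0]
        near = sweep_adjacent_genes(config, genes)
        inside = [
            g for g in genes
            if g.chrom == region.chrom
            and g.start >= region.start_bp and g.end <= region.end_bp
        ]
        far = [g for g in genes if g.gene_id not in near]
        assert inside and near and far
        assert {g.gene_id for g in inside} <= near

    def test_planted_term_covers_exactly_sweep_genes(self):
        from sweepscan.simulate import make_term_map

        config = SimulationConfig(seed=0)
        genes = tile_genes(config)
        term_map = make_term_map(config, genes)
        with_term = set(term_map.loc[term_map["term_id"] == "T_sweep", "gene_id"])
        assert with_term == sweep_adjacent_genes(config, genes)
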