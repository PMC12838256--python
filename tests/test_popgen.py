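"""Weir-Cockerham components, per-site pi, and window aggregation."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import aggregate_windows, make_windows, site_components, wc_components
from sweepscan.containers import MISSING
from sweepscan.popgen import theta_per_site

from tests.conftest import make_site
from tests.oracles import pi_bruteforce, wc_components_oracle


def _random_pop(rng, n_max=12):
    n = rng.integers(2, n_max + 1)
    gts = rng.integers(0, 3, size=n)
    return list(gts)


class TestWeirCockerham:
    def test_matches_independent_transcription_on_random_configs(self):
        """a, b, c agree with a scalar step-by-step formula transcription."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            case = _random_pop(rng)
            control = _random_pop(rng)
            oracle = wc_components_oracle(case, control)
            got = wc_components(np.array([case]), np.array([control])).iloc[0]
            assert oracle is not None
            a, b, c = oracle
            np.testing.assert_allclose(
                [got["a"], got["b"], got["c"]], [a, b, c], rtol=1e-12, atol=1e-15
            )
            checked += 1

    def test_complete_fixed_difference_gives_theta_one(self):
        case = np.full((1, 10), 2, dtype=np.int8)
        control = np.zeros((1, 10), dtype=np.int8)
        comp = wc_components(case, control)
        theta = theta_per_site(comp)[0]
        assert theta == pytest.approx(1.0, abs=1e-12)
        assert comp.loc[0, "b"] == pytest.approx(0.0, abs=1e-12)
        assert comp.loc[0, "c"] == 0.0

    def test_no_differentiation_mean_theta_near_zero(self):
        """Identical HWE populations: mean per-site theta ~ 0 over many sites."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=4000)
        gt_a = rng.binomial(2, p[:, None], size=(4000, 40)).astype(np.int8)
        gt_b = rng.binomial(2, p[:, None], size=(4000, 40)).astype(np.int8)
        comp = wc_components(gt_a, gt_b)
        theta = theta_per_site(comp)
        assert abs(np.nanmean(theta)) < 0.01

    def test_worked_small_configuration(self):
        """The 4-vs-4 example genotypes agree with the transcription oracle."""
        case = [0, 1, 2, 1]
        control = [0, 0, 1, 0]
        a, b, c = wc_components_oracle(case, control)
        got = wc_components(np.array([case]), np.array([control])).iloc[0]
        assert got["a"] == pytest.approx(a, rel=1e-12)
        assert got["b"] == pytest.approx(b, rel=1e-12)
        assert got["c"] == pytest.approx(c, rel=1e-12)
        denom = a + b + c
        assert theta_per_site(pd.DataFrame([got]))[0] == pytest.approx(
            a / denom, rel=1e-12
        )

    def test_missing_calls_excluded_and_small_groups_na(self):
        site = make_site([0, 1, MISSING, 2, MISSING, 0])
        row = site_components(site, case_idx=[0, 1, 2], control_idx=[3, 4, 5])
        # case has 2 called, control has 2 called -> defined
        assert row["n_case_called"] == 2
        assert row["n_control_called"] == 2
        row2 = site_components(site, case_idx=[0, 2], control_idx=[3, 4, 5])
        assert np.isnan(row2["a"])  # only one called case diploid


class TestPi:
    def test_matches_bruteforce_pairwise_differences(self):
        """Per-site pi equals mean pairwise haplotype difference, m <= 12."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(2, 7)  # m = 2n <= 12
            gts = list(rng.integers(0, 3, size=n))
            expected = pi_bruteforce(gts)
            comp = wc_components(
                np.array([gts]), np.array([[0, 1]])  # control side irrelevant
            )
            assert comp.loc[0, "pi_case"] == pytest.approx(expected, abs=1e-12)

    def test_two_diploids_opposite_homozygotes(self):
        # haplotypes A,A,T,T: 4 differing pairs of C(4,2)=6
        comp = wc_components(np.array([[0, 2]]), np.array([[0, 0]]))
        assert comp.loc[0, "pi_case"] == pytest.approx(4 / 6, abs=1e-15)


class TestWindows:
    def test_stride_enumeration(self):
        windows = make_windows({"chr1": 250_000})
        assert list(map(tuple, windows[["start", "end"]].to_numpy())) == [
            (0, 100_000),
            (50_000, 150_000),
            (100_000, 200_000),
            (150_000, 250_000),
        ]
        assert not windows["partial"].any()

    def test_single_window_chromosome(self):
        windows = make_windows({"chr1": 100_000})
        assert len(windows) == 1

    def test_partial_window_emitted_when_tail_exists(self):
        windows = make_windows({"chr1": 260_000})
        last = windows.iloc[-1]
        assert (last["start"], last["end"], last["partial"]) == (200_000, 260_000, True)

    def test_nonoverlapping_when_step_equals_window(self):
        windows = make_windows({"chr1": 300_000}, window_bp=100_000, step_bp=100_000)
        assert len(windows) == 3
        assert (windows["start"].to_numpy() == [0, 100_000, 200_000]).all()

    def test_nonpositive_sizes_rejected(self):
        from sweepscan import ConfigurationError

        with pytest.raises(ConfigurationError):
            make_windows({"chr1": 100_000}, window_bp=0)


def _components_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "a", "b", "c",
            "pi_case", "pi_control", "n_case_called", "n_control_called",
        ],
    )


class TestAggregation:
    def test_snp_on_overlap_counted_in_both_windows(self):
        comp = _components_frame([("chr1", 60_000, 0.1, 0.2, 0.3, 0.4, 0.5, 10, 10)])
        windows = make_windows({"chr1": 200_000})
        stats = aggregate_windows(comp, windows)
        hit = stats[stats["n_snps"] > 0]
        assert list(hit["start"]) == [0, 50_000]
        # window pi divides by the 100 kb span
        np.testing.assert_allclose(hit["pi_case"], 0.4 / 100_000)

    def test_window_fst_is_ratio_of_sums(self):
        rows = [
            ("chr1", 10_000, 0.01, 0.02, 0.03, 0.1, 0.2, 10, 10),
            ("chr1", 20_000, 0.05, 0.01, 0.02, 0.3, 0.1, 10, 10),
            ("chr1", 30_000, -0.01, 0.03, 0.01, 0.2, 0.2, 10, 10),
        ]
        comp = _components_frame(rows)
        windows = make_windows({"chr1": 100_000})
        stats = aggregate_windows(comp, windows)
        a = 0.01 + 0.05 - 0.01
        denom = sum(sum(r[2:5]) for r in rows)
        assert stats.loc[0, "fst"] == pytest.approx(a / denom, rel=1e-12)
        assert stats.loc[0, "pi_ratio"] == pytest.approx(
            (0.2 + 0.1 + 0.2) / (0.1 + 0.3 + 0.2), rel=1e-12
        )

    def test_empty_and_all_na_windows_are_na(self):
        comp = _components_frame(
            [("chr1", 10_000, np.nan, np.nan, np.nan, np.nan, np.nan, 1, 1)]
        )
        windows = make_windows({"chr1": 100_000})
        stats = aggregate_windows(comp, windows)
        assert stats.loc[0, "n_snps"] == 0
        assert np.isnan(stats.loc[0, "fst"])
        assert np.isnan(stats.loc[0, "pi_ratio"])

    def test_unsorted_input_rejected(self):
        comp = _components_frame(
            [
                ("chr1", 20_000, 0.1, 0.1, 0.1, 0.1, 0.1, 5, 5),
                ("chr1", 10_000, 0.1, 0.1, 0.1, 0.1, 0.1, 5, 5),
            ]
        )
        with pytest.raises(ValueError, match="not sorted"):
            aggregate_windows(comp, make_windows({"chr1": 100_000}))

    def test_label_swap_symmetry(self, default_cohort):
        """Swapping case/control leaves window FST unchanged, inverts pi-ratio."""
        from sweepscan import window_scan

        config, table, manifest = default_cohort
        sub = table.take_sites(np.arange(0, table.n_sites, 7))
        _, fwd = window_scan(
            sub, manifest["case_ids"], manifest["control_ids"], config.chrom_lengths
        )
        _, rev = window_scan(
            sub, manifest["control_ids"], manifest["case_ids"], config.chrom_lengths
        )
        np.testing.assert_allclose(fwd["fst"], rev["fst"], rtol=1e-9, equal_nan=True)
        both = ~(fwd["pi_ratio"].isna() | rev["pi_ratio"].isna())
        np.testing.assert_allclose(
            fwd.loc[both, "pi_ratio"], 1.0 / rev.loc[both, "pi_ratio"], rtol=1e-9
        )

    def test_monomorphic_sites_contribute_nothing(self):
        base = [("chr1", 10_000, 0.02, 0.01, 0.01, 0.1, 0.2, 10, 10)]
        mono = base + [("chr1", 20_000, 0.0, 0.0, 0.0, 0.0, 0.0, 10, 10)]
        windows = make_windows({"chr1": 100_000})
        with_mono = aggregate_windows(_components_frame(mono), windows)
        without = aggregate_windows(_components_frame(base), windows)
        assert with_mono.loc[0, "fst"] == pytest.approx(without.loc[0, "fst"])
        assert with_mono.loc[0, "pi_case"] == pytest.approx(without.loc[0, "pi_case"])
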