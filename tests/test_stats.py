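"""Tests for the assay statistics: oracles, conventions, calibration at small scale."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mateguard.simulate import AssayDesign, generate_md_assay
from mateguard.stats import (
    bootstrap_mean_difference,
    compare_experiment,
    courtship_index,
    dunns_multiple_comparison,
    filter_within_window,
    kruskal_wallis,
    ks_normality,
    locomotion_velocity,
    normalize_fluorescence,
    percent_reduction,
    significance_annotation,
    students_t,
    welch_t,
)

from _oracles import brute_dunn_z, brute_kruskal_h

# ---------------------------------------------------------------------------


class TestFilter:
    def _table(self, latencies):
        return pd.DataFrame(
            {
                "fly_id": [f"f{i}" for i in range(len(latencies))],
                "copulation_latency_s": latencies,
                "mating_duration_s": [1000] * len(latencies),
            }
        )

    def test_boundary_inclusive(self):
        t = self._table([100, 3599, 3600, 3601, 7200])
        out = filter_within_window(t, 3600)
        assert len(out) == 3
        assert out.included.all()

    def test_noop_when_all_within(self):
        t = self._table([10, 20, 30])
        out = filter_within_window(t)
        assert list(out.fly_id) == list(t.fly_id)

    def test_empty_table_ok(self):
        out = filter_within_window(self._table([]))
        assert len(out) == 0

    def test_missing_column_is_schema_error(self):
        with pytest.raises(KeyError):
            filter_within_window(pd.DataFrame({"x": [1]}))

    def test_idempotent(self):
        t = self._table([100, 4000, 200])
        once = filter_within_window(t)
        twice = filter_within_window(once)
        assert once.equals(twice)


class TestEffectSize:
    def test_forced_arithmetic(self):
        assert percent_reduction([100.0] * 5, [87.6] * 5) == pytest.approx(12.4)

    def test_identity(self):
        assert percent_reduction([3, 4, 5], [3, 4, 5]) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction([0.0, 0.0], [1.0])


class TestStudentsT:
    def test_hand_computed_example(self):
        res = students_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.0214, abs=1e-3)

    def test_identical_samples(self):
        res = students_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_degenerate_unequal_means(self):
        res = students_t([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.degenerate

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_pooled(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 20))
        b = rng.normal(0.5, 2, rng.integers(3, 20))
        ours = students_t(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=True)
        assert ours.t == pytest.approx(ref_t, rel=1e-10)
        assert ours.p == pytest.approx(ref_p, rel=1e-10)

    def test_welch_option_available(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0]
        ours = welch_t(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=False)
        assert ours.t == pytest.approx(ref_t, rel=1e-10)
        assert ours.p == pytest.approx(ref_p, rel=1e-10)


class TestKsNormality:
    def test_retains_normal_sample(self):
        x = np.random.default_rng(0).normal(10, 2, 500)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_rejects_exponential_sample(self):
        x = np.random.default_rng(1).exponential(1.0, 500)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_lognormal_mode(self):
        x = np.random.default_rng(2).lognormal(2.0, 0.5, 300)
        _, p_log = ks_normality(x, mode="lognormal")
        _, p_norm = ks_normality(x, mode="normal")
        assert p_log > 0.05 > p_norm

    def test_lognormal_mode_needs_positive_values(self):
        with pytest.raises(ValueError):
            ks_normality([-1.0, 1.0, 2.0, 3.0, 4.0], mode="lognormal")

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(ValueError):
            ks_normality([5.0] * 10)

    def test_uncorrected_mode_matches_scipy(self):
        x = np.random.default_rng(3).normal(0, 1, 50)
        d, p = ks_normality(x, corrected=False)
        ref = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestKruskalDunn:
    def test_h_matches_brute_force_no_ties(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(brute_kruskal_h(groups), rel=1e-12)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-12)

    def test_h_matches_brute_force_with_ties(self):
        groups = [[1, 2, 2], [2, 3, 4], [4, 4, 5]]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(brute_kruskal_h(groups), rel=1e-12)

    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_convention(self):
        assert kruskal_wallis([[2, 2], [2, 2]]) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            [[1, 1, 2], [2, 3], [4, 5, 6, 7]],
            [[3.2, 1.1], [4.5, 0.2, 9.9], [5.5]],
            [[1, 2, 3, 4], [2, 3, 4, 5], [3, 4, 5, 6]],
        ],
    )
    def test_dunn_z_matches_brute_force(self, groups):
        res = dunns_multiple_comparison(groups, control=None)
        pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
        for comp, (i, j) in zip(res.comparisons, pairs):
            assert comp.z == pytest.approx(brute_dunn_z(groups, i, j), rel=1e-10)

    def test_identical_pair_no_hash(self):
        res = dunns_multiple_comparison([[1, 2, 3], [1, 2, 3]], control=None)
        assert res.comparisons[0].z == pytest.approx(0.0, abs=1e-12)
        assert res.comparisons[0].p_adjusted == 1.0
        assert not res.comparisons[0].hash_mark

    def test_hash_iff_adjusted_p_below_threshold(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc, 1, 12) for loc in (0, 0.2, 3.0)]
        res = dunns_multiple_comparison(groups, control=0)
        for comp in res.comparisons:
            assert comp.hash_mark == (comp.p_adjusted < 0.05)
        assert any(c.hash_mark for c in res.comparisons)

    def test_control_vs_all_counts_comparisons(self):
        res = dunns_multiple_comparison([[1, 2], [3, 4], [5, 6]], control=0)
        assert len(res.comparisons) == 2
        res_all = dunns_multiple_comparison([[1, 2], [3, 4], [5, 6]], control=None)
        assert len(res_all.comparisons) == 3


class TestBootstrap:
    def test_seeded_determinism(self):
        a = np.arange(10.0)
        b = np.arange(10.0) + 2
        r1 = bootstrap_mean_difference(a, b, seed=5)
        r2 = bootstrap_mean_difference(a, b, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_degenerate_constant_groups(self):
        r = bootstrap_mean_difference([3.0] * 5, [3.0] * 5, seed=0)
        assert r.mean_difference == 0.0
        assert r.ci_low == r.ci_high == 0.0

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        r = bootstrap_mean_difference(a, b, seed=1)
        assert r.ci_low <= r.mean_difference <= r.ci_high

    def test_close_to_scipy_percentile_interval(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)
        ours = bootstrap_mean_difference(a, b, n_resamples=9999, seed=2)
        ref = sps.bootstrap(
            (a, b),
            lambda x, y, axis: np.mean(y, axis=axis) - np.mean(x, axis=axis),
            n_resamples=9999,
            confidence_level=0.95,
            method="percentile",
            random_state=np.random.default_rng(3),
        )
        assert ours.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.1)
        assert ours.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.1)

    def test_bca_variant_reasonable(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 25), rng.normal(1, 1, 25)
        perc = bootstrap_mean_difference(a, b, seed=4, method="percentile")
        bca = bootstrap_mean_difference(a, b, seed=4, method="bca")
        assert abs(bca.ci_low - perc.ci_low) < 0.3
        assert bca.ci_low < bca.mean_difference < bca.ci_high

    def test_resample_floor(self):
        with pytest.raises(ValueError):
            bootstrap_mean_difference([1, 2, 3], [4, 5, 6], n_resamples=50)


class TestAnnotationsAndMetrics:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"), (0.049, "*"), (0.05, "ns"), (0.2, "ns"), (1.0, "ns")],
    )
    def test_star_thresholds_strict(self, p, expected):
        assert significance_annotation(p) == expected

    def test_p_outside_unit_interval_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                significance_annotation(bad)

    def test_courtship_index(self):
        assert courtship_index(300, 600) == 0.5
        assert courtship_index(150, 600, time_to_mate_s=200) == 0.75
        assert courtship_index(0, 600) == 0.0
        with pytest.raises(ValueError):
            courtship_index(700, 600)

    def test_locomotion_velocity(self):
        assert locomotion_velocity(80, 10) == 8.0
        assert locomotion_velocity(0, 10) == 0.0
        with pytest.raises(ValueError):
            locomotion_velocity(10, 0)

    def test_normalize_fluorescence(self):
        assert normalize_fluorescence(200.0, 100.0) == 2.0
        assert normalize_fluorescence(50.0, 50.0) == 1.0
        with pytest.raises(ValueError):
            normalize_fluorescence(10.0, 0.0)


class TestCompareExperiment:
    def test_two_group_end_to_end(self):
        table = generate_md_assay(AssayDesign(seed=21, percent_reduction=15.0))
        comparison, estimation = compare_experiment(table, reference="naive", seed=1)
        assert comparison.group_labels[0] == "naive"
        assert comparison.stars == significance_annotation(comparison.p_value)
        # CI of (experienced - naive) and percent reduction must agree in sign
        assert (comparison.percent_reduction > 0) == (estimation.mean_difference < 0)

    def test_identical_groups_ns(self):
        table = generate_md_assay(AssayDesign(seed=22, percent_reduction=0.0))
        comparison, estimation = compare_experiment(table, reference="naive", seed=1)
        assert comparison.stars == "ns"
        assert estimation.ci_low < 0 < estimation.ci_high

    def test_multi_group_routes_to_kw_dunn(self):
        design = AssayDesign(
            groups=(
                ("CS_naive", "naive", 20),
                ("CS_2h", "naive", 20),
                ("CS_12h", "experienced", 20),
                ("CS_24h", "experienced", 20),
            ),
            percent_reduction=15.0,
            seed=23,
        )
        table = generate_md_assay(design)
        out = compare_experiment(
            table, group_by=("genotype",), reference="CS_naive", seed=1
        )
        assert len(out) == 3
        multi = out[2]
        assert len(multi.comparisons) == 3
        for comp in multi.comparisons:
            assert comp.pair[0] == "CS_naive"

    def test_missing_group_named_in_error(self):
        table = generate_md_assay(AssayDesign(seed=24))
        with pytest.raises(ValueError, match="virgin"):
            compare_experiment(table, groups=["naive", "virgin"])
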