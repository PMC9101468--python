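"""Bland-Altman, reliability, kappa, Wilcoxon, and plot-shape diagnostics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from timeuse_validation.agreement import (
    bland_altman,
    cronbach_alpha,
    interpret_alpha,
    interpret_kappa,
    shape_diagnostics,
    threshold_counts,
    weighted_kappa,
    wilcoxon_signed_rank,
)


class TestBlandAltman:
    def test_identity_inputs(self):
        res = bland_altman([3.0, 7.0, 11.0], [3.0, 7.0, 11.0])
        assert res.bias == 0 and res.sd_diff == 0
        assert (res.loa_low, res.loa_high) == (0, 0)
        assert res.ties == 3

    def test_constant_offset(self):
        res = bland_altman([10, 20, 30], [0, 10, 20])
        assert res.bias == 10 and res.sd_diff == 0
        assert (res.loa_low, res.loa_high) == (10, 10)
        assert res.counts_above_zero == 3

    def test_hand_computed_n2_case(self):
        # d = (-10, 10): bias 0, sd = |d1-d2|/sqrt(2) = 14.142...
        res = bland_altman([0, 10], [10, 0], multiplier=2)
        assert res.bias == 0
        assert res.sd_diff == pytest.approx(20 / math.sqrt(2))
        assert res.loa_low == pytest.approx(-2 * 20 / math.sqrt(2))  # -28.284
        assert res.loa_high == pytest.approx(2 * 20 / math.sqrt(2))  # 28.284

    def test_positive_bias_means_test_underestimates(self):
        res = bland_altman([100, 100], [40, 40])
        assert res.bias > 0

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        st.floats(-500, 500),
    )
    def test_antisymmetry_and_translation(self, values, shift):
        rng = np.random.default_rng(len(values))
        other = rng.uniform(-1e3, 1e3, len(values))
        a = bland_altman(values, other)
        b = bland_altman(other, values)
        assert b.bias == pytest.approx(-a.bias, abs=1e-9)
        assert b.loa_low == pytest.approx(-a.loa_high, abs=1e-8)
        # translating both inputs leaves the differences unchanged
        t = bland_altman(np.asarray(values) + shift, other + shift)
        assert t.bias == pytest.approx(a.bias, abs=1e-6)
        assert t.sd_diff == pytest.approx(a.sd_diff, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


class TestThresholdCounts:
    def test_all_within(self):
        (row,) = threshold_counts([0, 0, 0], [30])
        assert row["n_within"] == 3 and row["pct_within"] == 100

    def test_boundary_uses_lte(self):
        (row,) = threshold_counts([29, 31, -29], [30])
        assert row["n_within"] == 2

    def test_beyond_two_hours(self):
        (row,) = threshold_counts([121, -121, 119], [120])
        assert row["n_beyond"] == 2

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_counts([1.0], [0])


class TestCronbachAlpha:
    def test_duplicated_vector_gives_one(self):
        a = [10.0, 20.0, 35.0, 50.0]
        res = cronbach_alpha(a, a)
        assert res.alpha == pytest.approx(1.0)
        assert res.label == "suspect"  # > 0.95 on the benchmark scale

    def test_mirrored_vector_is_undefined(self):
        a = np.array([-1.0, 0.0, 1.0])
        res = cronbach_alpha(a, -a)
        assert not res.defined and math.isnan(res.alpha)
        assert res.label == "undefined"

    def test_independent_methods_alpha_near_zero(self):
        rng = np.random.default_rng(20240101)
        a = rng.normal(size=10_000)
        b = rng.normal(size=10_000)
        assert abs(cronbach_alpha(a, b).alpha) < 0.05

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        a = rng.normal(50, 10, 40)
        b = a + rng.normal(0, 8, 40)
        expected = pingouin.cronbach_alpha(
            data=pd.DataFrame({"a": a, "b": b})
        )[0]
        assert cronbach_alpha(a, b).alpha == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 50),
        seed=st.integers(0, 1000),
    )
    def test_shift_and_joint_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 5, 20)
        b = a + rng.normal(0, 3, 20)
        base = cronbach_alpha(a, b).alpha
        assert cronbach_alpha(a + shift, b).alpha == pytest.approx(base, abs=1e-6)
        assert cronbach_alpha(a * scale, b * scale).alpha == pytest.approx(
            base, abs=1e-6
        )

    def test_benchmark_labels(self):
        assert interpret_alpha(0.5) == "unacceptable"
        assert interpret_alpha(0.75) == "acceptable"
        assert interpret_alpha(0.85) == "moderate"
        assert interpret_alpha(0.92) == "high"
        assert interpret_alpha(0.97) == "suspect"


class TestWeightedKappa:
    def test_perfect_agreement(self):
        res = weighted_kappa([1, 2, 3, 2], [1, 2, 3, 2])
        assert res.kappa == pytest.approx(1.0)
        assert res.label == "almost perfect"

    def test_uniform_2x2_table_is_zero(self):
        a = [0, 0, 1, 1]
        b = [0, 1, 0, 1]
        assert weighted_kappa(a, b).kappa == pytest.approx(0.0)

    def test_hand_computed_5115_table(self):
        # counts ((5,1),(1,5)): linear-weight kappa = 2/3
        a = [0] * 6 + [1] * 6
        b = [0] * 5 + [1] + [0] + [1] * 5
        res = weighted_kappa(a, b, "linear")
        assert res.kappa == pytest.approx(2 / 3)
        assert res.label == "substantial"

    def test_quadratic_equals_linear_on_two_categories(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        lin = weighted_kappa(a, b, "linear").kappa
        quad = weighted_kappa(a, b, "quadratic").kappa
        assert lin == pytest.approx(quad)

    def test_half_integer_ratings_doubled(self):
        res = weighted_kappa([1.0, 1.5, 2.0], [1.0, 1.5, 2.0])
        assert res.kappa == pytest.approx(1.0)
        assert res.categories == (2, 3, 4)

    def test_single_category_flagged_undefined(self):
        res = weighted_kappa([2, 2, 2], [2, 2, 2])
        assert not res.defined and math.isnan(res.kappa)

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        a = rng.integers(0, 5, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 0, 4)
        for scheme in ("linear", "quadratic"):
            expected = sklearn_metrics.cohen_kappa_score(a, b, weights=scheme)
            assert weighted_kappa(a, b, scheme).kappa == pytest.approx(
                expected, abs=1e-10
            )

    def test_benchmark_labels(self):
        assert interpret_kappa(-0.1) == "poor"
        assert interpret_kappa(0.1) == "slight"
        assert interpret_kappa(0.3) == "fair"
        assert interpret_kappa(0.5) == "moderate"
        assert interpret_kappa(0.7) == "substantial"
        assert interpret_kappa(0.9) == "almost perfect"


def enumerate_signed_rank_p(diffs):
    """Brute-force exact p: statistic recomputed for every sign assignment."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.asarray(signs).dot(ranks)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge)), p_ge


class TestWilcoxon:
    def test_identical_inputs_not_testable(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert not res.testable and math.isnan(res.p_value)

    def test_three_positive_differences_exact(self):
        res = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert res.p_method == "exact"
        assert res.p_one_sided == pytest.approx(1 / 8)
        assert res.p_value == pytest.approx(1 / 4)

    def test_exact_matches_enumeration_random_datasets(self):
        rng = np.random.default_rng(99)
        for _ in range(250):
            n = int(rng.integers(2, 9))
            d = rng.integers(-5, 6, n)
            if not (d != 0).any():
                continue
            res = wilcoxon_signed_rank(d, np.zeros(n))
            p_two, p_one = enumerate_signed_rank_p(d)
            assert res.p_value == pytest.approx(p_two, abs=1e-12)
            assert res.p_one_sided == pytest.approx(p_one, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        d = rng.permutation([1.5, -2.5, 3.5, 4.25, -5.125, 6.75, 7.0625, -8.5])
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        expected = stats.wilcoxon(d, method="exact").pvalue
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0.3, 1, 60)
        res = wilcoxon_signed_rank(x, y, p_mode="normal_approx")
        expected = stats.wilcoxon(x, y, correction=True, method="approx").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-6)

    def test_pratt_rule_keeps_zero_ranks_out_of_statistic(self):
        x = np.array([0.0, 1.0, 2.0, -3.0])
        y = np.zeros(4)
        drop = wilcoxon_signed_rank(x, y, zero_rule="drop")
        pratt = wilcoxon_signed_rank(x, y, zero_rule="pratt")
        assert drop.n_eff == pratt.n_eff == 3
        # under pratt, the zero takes rank 1, pushing non-zero ranks up
        assert pratt.statistic == drop.statistic + 2

    def test_pratt_exact_matches_enumeration(self):
        # oracle: ranks from |d| including zeros, signs enumerated over non-zeros
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            d = rng.integers(-4, 5, n)
            if not (d != 0).any():
                continue
            ranks_all = stats.rankdata(np.abs(d))
            active = ranks_all[d != 0]
            w_obs = active[d[d != 0] > 0].sum()
            ws = np.asarray(
                [
                    np.asarray(signs).dot(active)
                    for signs in itertools.product([0, 1], repeat=active.size)
                ]
            )
            p_two = min(
                1.0,
                2 * min(np.mean(ws <= w_obs + 1e-9), np.mean(ws >= w_obs - 1e-9)),
            )
            res = wilcoxon_signed_rank(d, np.zeros(n), zero_rule="pratt")
            assert res.p_value == pytest.approx(p_two, abs=1e-12)


class TestShapeDiagnostics:
    def _ba(self, means, diffs):
        # synthesise criterion/test pairs with the desired means and differences
        c = means + np.asarray(diffs) / 2
        t = means - np.asarray(diffs) / 2
        return bland_altman(c, t)

    def test_cloud_for_homoscedastic_no_trend(self):
        # cohort-scale n: both component tests at the 5% level, so roughly
        # 0.95^2 of null replicates should classify as cloud
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(500):
            means = rng.uniform(0, 100, 175)
            diffs = rng.normal(0, 5, 175)
            if shape_diagnostics(self._ba(means, diffs)).classification == "cloud":
                hits += 1
        assert hits >= 450  # >= 90% of replicates

    def test_sloped_for_linear_trend(self):
        rng = np.random.default_rng(13)
        means = rng.uniform(0, 100, 80)
        diffs = -0.5 * means + rng.normal(0, 3, 80)
        assert shape_diagnostics(self._ba(means, diffs)).classification == "sloped"

    def test_fan_for_proportional_spread(self):
        rng = np.random.default_rng(14)
        means = rng.uniform(1, 100, 300)
        diffs = rng.normal(0, 0.2 * means)
        assert shape_diagnostics(self._ba(means, diffs)).classification in (
            "fan",
            "fan+sloped",
        )

    def test_constant_means_flagged(self):
        res = bland_altman([12, 8, 11, 9], [8, 12, 9, 11])
        diag = shape_diagnostics(res)
        assert not diag.defined and diag.classification == "undefined"
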