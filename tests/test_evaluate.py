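"""Correlation metrics, per-branch F1, and rank tests on DP scores."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from branchtime import ValidationError, branch_f1, correlations, dp_group_tests
from branchtime.evaluate import kendall_tau_pairwise
from oracles import kendall_pairs


class TestCorrelations:
    def test_perfect_agreement(self):
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.7])
        c = correlations(x, x)
        assert (c.pearson, c.spearman, c.kendall) == pytest.approx((1, 1, 1))

    def test_perfect_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        c = correlations(-x, x)
        assert (c.pearson, c.spearman, c.kendall) == pytest.approx((-1, -1, -1))

    def test_kendall_five_point_fixture(self):
        # (1,2,3,5,4) vs (1,2,3,4,5): 9 concordant, 1 discordant over 10 pairs
        c = correlations(np.array([1, 2, 3, 5, 4.0]), np.array([1, 2, 3, 4, 5.0]))
        assert c.kendall == pytest.approx(0.8, abs=1e-6)

    def test_pairwise_formula_equals_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert kendall_tau_pairwise(x, y) == pytest.approx(
                kendall_pairs(x, y), rel=1e-12)

    def test_pairwise_equals_standard_tau_on_all_small_permutations(self):
        """Without ties the ordered-pair statistic is exactly Kendall's tau."""
        base = np.arange(5, dtype=float)
        for perm in itertools.permutations(range(5)):
            x = np.array(perm, dtype=float)
            expected = stats.kendalltau(x, base).statistic
            assert kendall_tau_pairwise(x, base) == pytest.approx(expected, rel=1e-12)

    def test_ties_drop_from_numerator_only(self):
        # (1,1,2) vs (1,2,3): pairs (0,2),(1,2) concordant-ish; pair (0,1) tied in x
        c = correlations(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert c.kendall == pytest.approx(4 / 6, rel=1e-12)
        assert c.kendall_b == pytest.approx(
            stats.kendalltau(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0])).statistic)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_spearman_is_pearson_on_ranks(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        c = correlations(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert c.spearman == pytest.approx(stats.pearsonr(rx, ry).statistic, rel=1e-9)

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            c = correlations(np.ones(5), np.arange(5.0))
        assert np.isnan(c.pearson) and np.isnan(c.spearman) and np.isnan(c.kendall)

    def test_short_and_nan_inputs_rejected(self):
        with pytest.raises(ValidationError):
            correlations(np.ones(2), np.ones(2))
        with pytest.raises(ValidationError):
            correlations(np.array([1.0, np.nan, 2.0]), np.arange(3.0))


class TestBranchF1:
    def test_perfect_prediction(self):
        truth = np.array([1, 1, 2, 2])
        c = branch_f1(truth, truth, 1)
        assert (c.precision, c.recall, c.f1) == (1.0, 1.0, 1.0)

    def test_constructed_confusion(self):
        # branch 1: tp=8, fp=2, fn=2 -> precision = recall = f1 = 0.8
        truth = np.array([1] * 10 + [2] * 2)
        pred = np.array([1] * 8 + [2] * 2 + [1] * 2)
        c = branch_f1(pred, truth, 1)
        assert (c.tp, c.fp, c.fn) == (8, 2, 2)
        assert (c.precision, c.recall, c.f1) == pytest.approx((0.8, 0.8, 0.8))

    def test_nothing_predicted_gives_zeros(self):
        truth = np.array([1, 1, 2])
        pred = np.array([2, 2, 2])
        c = branch_f1(pred, truth, 1)
        assert (c.precision, c.recall, c.f1) == (0.0, 0.0, 0.0)

    def test_progenitors_count_as_negative(self):
        truth = np.array([1, 1, 2])
        pred = np.array([1, 0, 0])  # sentinel 0 = progenitor
        c = branch_f1(pred, truth, 1)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_invariant_to_relabeling_other_branches(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 4, 30)
        pred = rng.integers(0, 4, 30)
        c1 = branch_f1(pred, truth, 1)
        relabeled = np.where(pred == 2, 9, np.where(pred == 3, 2, pred))
        c2 = branch_f1(relabeled, truth, 1)
        assert (c1.tp, c1.fp, c1.fn) == (c2.tp, c2.fp, c2.fn)


class TestDpGroupTests:
    def test_identical_groups_show_no_effect(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        kw_stat, kw_p, mwu = dp_group_tests(vals, labels, [("a", "b")])
        assert kw_p > 0.9
        assert 0.3 < mwu[("a", "b")] < 0.7

    def test_complete_separation_is_significant(self):
        dp = np.concatenate([np.linspace(2, 3, 20), np.linspace(0, 1, 20)])
        labels = np.array(["early"] * 20 + ["late"] * 20)
        _, kw_p, mwu = dp_group_tests(dp, labels, [("early", "late")])
        assert mwu[("early", "late")] < 1e-3
        assert kw_p < 1e-3

    def test_wrong_direction_is_not_significant(self):
        dp = np.concatenate([np.linspace(0, 1, 20), np.linspace(2, 3, 20)])
        labels = np.array(["early"] * 20 + ["late"] * 20)
        _, _, mwu = dp_group_tests(dp, labels, [("early", "late")])
        assert mwu[("early", "late")] > 0.99

    def test_two_groups_kw_equals_two_sided_mwu(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(0.6, 1.0, 25)
        dp = np.concatenate([a, b])
        labels = np.array(["a"] * 25 + ["b"] * 25)
        kw_stat, kw_p, _ = dp_group_tests(dp, labels, [])
        two_sided = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue
        assert kw_p == pytest.approx(two_sided, abs=0.01)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            dp_group_tests(np.arange(4.0), np.array(["a", "a", "a", "b"]), [])
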