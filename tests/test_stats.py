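"""Per-feature tests, permutation nulls, feature selection, H/L screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as sps

from adaptseq.stats import (
    anova_f_pvalues,
    count_significant,
    ks_2samp_vectorized,
    plus_one_pvalue,
    select_features,
    select_high_low,
    significance_permutation_test,
    two_group_tests,
)


class TestAnova:
    def test_constant_feature_p_one(self):
        X = np.vstack([np.full(6, 3.0), [1, 2, 3, 4, 5, 6.0]])
        p = anova_f_pvalues(X, ["a", "a", "a", "b", "b", "b"])
        assert p[0] == 1.0
        assert p[1] < 1.0

    def test_identical_groups_p_one(self):
        X = np.array([[1.0, 2, 3, 1, 2, 3]])
        p = anova_f_pvalues(X, ["a"] * 3 + ["b"] * 3)
        assert p[0] == pytest.approx(1.0)

    def test_matches_scipy_f_oneway(self, rng):
        X = rng.lognormal(0, 1, (50, 12))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        p = anova_f_pvalues(X, labels)
        ref = [sps.f_oneway(x[:4], x[4:8], x[8:]).pvalue for x in X]
        assert np.allclose(p, ref, rtol=1e-9)

    def test_two_groups_equal_squared_t(self, rng):
        # F with 2 groups is the square of the pooled-variance t statistic
        X = rng.normal(0, 1, (30, 10))
        labels = ["a"] * 5 + ["b"] * 5
        p_f = anova_f_pvalues(X, labels)
        p_t = sps.ttest_ind(X[:, :5], X[:, 5:], axis=1, equal_var=True).pvalue
        assert np.allclose(p_f, p_t, rtol=1e-9)

    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            anova_f_pvalues(np.ones((2, 4)), ["a"] * 4)


class TestCountSignificant:
    def test_strict_inequality(self):
        assert count_significant([0.01, 0.05, 0.9], alpha=0.05) == 1

    def test_empty(self):
        assert count_significant([]) == 0

    def test_alpha_one_saturates(self):
        assert count_significant([0.2, 0.9, 0.99], alpha=1.0) == 3

    @given(hst.integers(0, 2**16))
    def test_monotone_in_alpha(self, seed):
        p = np.random.default_rng(seed).uniform(size=30)
        counts = [count_significant(p, a) for a in (0.01, 0.05, 0.2, 1.0)]
        assert counts == sorted(counts)


class TestPlusOne:
    def test_never_zero(self):
        assert plus_one_pvalue(100.0, np.zeros(99)) == pytest.approx(1 / 100)

    def test_observed_below_all_nulls(self):
        assert plus_one_pvalue(0.0, np.ones(10)) == 1.0


class TestSignificancePermutation:
    def test_observed_matches_direct_count(self, rng):
        X = rng.lognormal(0, 1, (200, 18))
        labels = np.repeat(["a", "b", "c"], 6)
        res = significance_permutation_test(X, labels, n_perm=50, seed=1)
        assert res.observed == count_significant(anova_f_pvalues(X, labels))
        assert len(res.null_values) == 50
        assert 0 < res.p_value <= 1

    def test_invariant_to_feature_order_and_label_names(self, rng):
        X = rng.lognormal(0, 1, (100, 12))
        labels = np.repeat(["a", "b", "c"], 4)
        res1 = significance_permutation_test(X, labels, n_perm=30, seed=7)
        res2 = significance_permutation_test(X[::-1], labels, n_perm=30, seed=7)
        renamed = np.where(labels == "a", "zz", labels)
        res3 = significance_permutation_test(X, renamed, n_perm=30, seed=7)
        assert res1.observed == res2.observed == res3.observed
        assert res1.null_values == res2.null_values

    def test_null_block_matches_per_permutation_anova(self, rng):
        # the vectorized null must equal re-running the ANOVA on the same
        # label permutations drawn from the same generator state
        X = rng.lognormal(0, 1, (40, 12))
        labels = np.repeat(["a", "b"], 6)
        res = significance_permutation_test(X, labels, n_perm=25, seed=13)
        check = np.random.default_rng(13)
        labels_arr = np.asarray(labels)
        expect = []
        for _ in range(25):
            perm = check.permutation(12)
            expect.append(count_significant(anova_f_pvalues(X, labels_arr[perm])))
        assert res.null_values == [float(v) for v in expect]

    def test_signal_detected(self, rng):
        X = rng.normal(0, 1, (100, 18))
        X[:30, :6] += 2.0  # 30 features separate group a
        labels = np.repeat(["a", "b", "c"], 6)
        res = significance_permutation_test(X, labels, n_perm=99, seed=3)
        assert res.p_value == pytest.approx(1 / 100)


class TestTwoGroupTests:
    def test_identical_groups_nonsignificant(self, rng):
        half = rng.lognormal(0, 1, (30, 4))
        X = np.hstack([half, half])
        res = two_group_tests(X, ["a"] * 4 + ["b"] * 4)
        assert (res["p_t"] > 0.99).all()
        assert (res["p_wilcoxon"] > 0.99).all()
        assert (res["p_ks"] > 0.99).all()
        assert np.allclose(res["fold_change"], 1.0)

    def test_wilcoxon_exact_small_sample(self):
        X = np.array([[1.0, 2, 3, 4, 5, 6]])
        res = two_group_tests(X, ["a"] * 3 + ["b"] * 3)
        assert res["p_wilcoxon"][0] == pytest.approx(0.1)

    def test_ks_disjoint_supports_maximal(self):
        d, p = ks_2samp_vectorized(np.array([[1.0, 2, 3]]), np.array([[10.0, 11, 12]]))
        assert d[0] == 1.0

    def test_ks_matches_scipy_asymptotic(self, rng):
        a = rng.lognormal(0, 1, (100, 20))
        b = rng.lognormal(0.4, 1, (100, 25))
        d, p = ks_2samp_vectorized(a, b)
        ref = [sps.ks_2samp(a[i], b[i], method="asymp") for i in range(100)]
        assert np.allclose(d, [r.statistic for r in ref])
        assert np.allclose(p, [r.pvalue for r in ref])

    def test_ks_with_ties_matches_scipy(self, rng):
        a = rng.poisson(2, (50, 15)).astype(float)
        b = rng.poisson(3, (50, 18)).astype(float)
        d, _ = ks_2samp_vectorized(a, b)
        ref = [sps.ks_2samp(a[i], b[i]).statistic for i in range(50)]
        assert np.allclose(d, ref)

    def test_welch_t_matches_scipy(self, rng):
        X = rng.lognormal(0, 1, (40, 14))
        labels = ["a"] * 6 + ["b"] * 8
        res = two_group_tests(X, labels)
        ref = sps.ttest_ind(X[:, :6], X[:, 6:], axis=1, equal_var=False).pvalue
        assert np.allclose(res["p_t"], ref)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_tests(np.ones((3, 3)), ["a", "a", "b"])


class TestSelectFeatures:
    def _tests_df(self, p_t, p_w, p_ks, fc):
        return pd.DataFrame(
            {"p_t": p_t, "p_wilcoxon": p_w, "p_ks": p_ks, "fold_change": fc}
        )

    def test_union_semantics_single_test_passes(self):
        df = self._tests_df([0.9], [0.9], [0.01], [1.0])
        assert select_features(df).selected[0]

    def test_fold_change_boundary_strict(self):
        df = self._tests_df([0.9], [0.9], [0.9], [1.2])
        assert not select_features(df, fc_threshold=1.2).selected[0]
        df2 = self._tests_df([0.9], [0.9], [0.9], [1.2000001])
        assert select_features(df2, fc_threshold=1.2).selected[0]

    def test_downward_fold_change_selected(self):
        df = self._tests_df([0.9], [0.9], [0.9], [1 / 1.5])
        assert select_features(df).selected[0]

    def test_intersection_mode(self):
        df = self._tests_df([0.01, 0.01], [0.01, 0.9], [0.01, 0.01], [2.0, 2.0])
        sel = select_features(df, mode="intersection")
        assert sel.selected.tolist() == [True, False]

    def test_null_union_rate_exceeds_single_alpha(self, rng):
        X = rng.lognormal(0, 1, (2000, 40))
        res = two_group_tests(X, ["a"] * 20 + ["b"] * 20, pseudocount=1.0)
        frac = select_features(res).selected.mean()
        assert frac > 0.05  # union of several tests is anticonservative


class TestHighLow:
    def test_enumerated_ratios(self):
        ref = np.ones(6)
        sample = np.array([10, 6, 5, 1, 0.2, 0.1])
        high, low = select_high_low(sample, ref, fold=5)
        assert list(high) == [0, 1, 2]
        assert list(low) == [4, 5]

    def test_boundary_inclusive(self):
        high, low = select_high_low([5.0], [1.0], fold=5)
        assert list(high) == [0]

    def test_unit_ratio_unlabelled(self):
        high, low = select_high_low([1.0], [1.0], fold=5)
        assert len(high) == 0 and len(low) == 0
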