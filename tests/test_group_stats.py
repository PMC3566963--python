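"""Two-group tests, multiple-testing correction, filtering, correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from metadiff import (
    AbundanceTable,
    UsageError,
    ValidationError,
    adjust_pvalues,
    compare_groups,
    correlate_with_metadata,
    filter_results,
    mann_whitney,
    normality_and_variance_diagnostics,
    normalize_relative,
    t_test,
)
from metadiff.group_stats import default_pseudocount
from metadiff.metadata import SampleGroups, SampleMetadata


def exact_mw_oracle(x, y):
    """Two-sided exact p by enumerating all C(n+m, n) group labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(tuple(range(n)))
    center = n * len(y) / 2
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n)]
    tail = sum(abs(u - center) >= abs(u_obs - center) - 1e-12 for u in us)
    return min(1.0, tail / len(us))


class TestMannWhitney:
    def test_separated_groups_worked_example(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)
        assert res.exact

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.random(int(rng.integers(1, 8)))
            y = rng.random(int(rng.integers(1, 8)))
            a, b = mann_whitney(x, y), mann_whitney(y, x)
            assert a.pvalue == pytest.approx(b.pvalue)
            assert a.statistic == pytest.approx(len(x) * len(y) - b.statistic)

    def test_fully_tied_data_gives_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).pvalue == pytest.approx(1.0, abs=0.05)
        assert mann_whitney([5, 5, 5], [5, 5, 5]).pvalue == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n, m = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            x = rng.permutation(n + m)[:n].astype(float)  # tie-free ranks
            y = np.setdiff1d(np.arange(n + m), x).astype(float)
            res = mann_whitney(x, y)
            assert res.exact
            assert res.pvalue == pytest.approx(exact_mw_oracle(x, y))

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.random(15)
        y = rng.random(18) + 0.2
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert not res.exact
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-10)

    def test_tied_data_uses_corrected_approximation(self):
        x = [1, 1, 2, 2, 3]
        y = [2, 3, 3, 4, 4]
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(UsageError):
            mann_whitney([], [1.0])


class TestTTest:
    def test_pooled_worked_example(self):
        res = t_test([1, 2, 3], [4, 5, 6], variant="pooled")
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4
        assert res.pvalue == pytest.approx(0.0214, abs=1e-3)

    def test_identical_groups(self):
        res = t_test([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_scale_invariance(self):
        a = t_test([1, 2, 3], [4, 5, 7])
        b = t_test([10, 20, 30], [40, 50, 70])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_zero_variance_different_means_is_degenerate(self):
        res = t_test([1, 1, 1], [2, 2, 2])
        assert res.degenerate and res.pvalue == 0.0

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(6), rng.random(9) * 3
        res = t_test(x, y, variant="welch")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.df == pytest.approx(ref.df)

    def test_too_small_group_rejected(self):
        with pytest.raises(UsageError):
            t_test([1.0], [1.0, 2.0])


class TestDiagnostics:
    def test_shapiro_n3_closed_form(self):
        report = normality_and_variance_diagnostics([1, 2, 3], [4, 5, 7])
        assert report.shapiro_w_x == pytest.approx(1.0, abs=1e-6)

    def test_equal_shape_groups_give_null_variance_stats(self):
        report = normality_and_variance_diagnostics([1, 2, 3], [4, 5, 6])
        assert report.bartlett_stat == pytest.approx(0.0, abs=1e-12)
        assert report.bartlett_p == pytest.approx(1.0)
        assert report.levene_stat == pytest.approx(0.0, abs=1e-12)
        assert report.levene_p == pytest.approx(1.0)

    def test_small_samples_marked_unavailable_not_fatal(self):
        report = normality_and_variance_diagnostics([1.0, 2.0], [3.0, 4.0])
        assert report.shapiro_w_x is None
        assert any("Shapiro" in note for note in report.notes)
        assert report.levene_stat is not None


class TestAdjust:
    def test_bh_worked_vector(self):
        out = adjust_pvalues([0.01, 0.04, 0.03, 0.005], "bh")
        np.testing.assert_allclose(out, [0.02, 0.04, 0.04, 0.02])

    def test_bonferroni_multiplies_and_caps(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.4], "bonferroni"), [0.02, 0.8])
        np.testing.assert_allclose(adjust_pvalues([0.6, 0.7], "bonferroni"), [1.0, 1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.sampled_from(["bh", "bonferroni"]))
    def test_dominance_property(self, pvals, method):
        p = np.array(pvals)
        out = adjust_pvalues(p, method)
        assert (out >= p - 1e-15).all() and (out <= 1.0).all()

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 200)))
            mine = adjust_pvalues(p, "bh")
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_bh_rejections_match_step_up_rule(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 100)))
            for alpha in (0.05, 0.1, 0.2):
                adj = adjust_pvalues(p, "bh")
                # textbook rule: reject all p <= p_(k), k largest i with p_(i) <= i*alpha/m
                m = len(p)
                srt = np.sort(p)
                ks = np.where(srt <= (np.arange(1, m + 1) * alpha / m))[0]
                expected = np.zeros(m, bool) if ks.size == 0 else p <= srt[ks.max()]
                np.testing.assert_array_equal(adj <= alpha, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.1, 1.2], "bh")


def _rel_table(matrix, samples):
    df = pd.DataFrame(matrix, index=[f"f{i}" for i in range(len(matrix))], columns=samples)
    return normalize_relative(AbundanceTable(df))


class TestCompareGroups:
    def test_single_feature_fold_change(self):
        table = AbundanceTable(
            pd.DataFrame([[0.2, 0.2, 0.1, 0.1]], index=["f0"],
                         columns=["a1", "a2", "b1", "b2"]),
            mode="relative", _strict=False)
        groups = SampleGroups("A", ("a1", "a2"), "B", ("b1", "b2"))
        res = compare_groups(table, groups, pseudocount=0.0)
        assert res.loc["f0", "fold_change"] == pytest.approx(2.0)
        assert res.loc["f0", "abs_fold_change"] == pytest.approx(2.0)

    def test_fold_change_reciprocal_under_swap(self, small_fixture, small_groups):
        _, _, table, _, _ = small_fixture
        rel = normalize_relative(table)
        res_ab = compare_groups(rel, small_groups, pseudocount=0.0)
        swapped = SampleGroups(small_groups.label_b, small_groups.samples_b,
                               small_groups.label_a, small_groups.samples_a)
        res_ba = compare_groups(rel, swapped, pseudocount=0.0)
        fc = (res_ab["fold_change"] * res_ba["fold_change"]).dropna()
        finite = fc[np.isfinite(fc)]
        np.testing.assert_allclose(finite, 1.0, rtol=1e-9)
        pd.testing.assert_series_equal(
            res_ab["abs_fold_change"].sort_index(), res_ba["abs_fold_change"].sort_index())

    def test_identical_groups_give_p_one(self):
        table = _rel_table(np.tile([[1.0, 2.0], [3.0, 4.0]], 2), ["a1", "a2", "b1", "b2"])
        groups = SampleGroups("A", ("a1", "a2"), "B", ("b1", "b2"))
        res = compare_groups(table, groups)
        assert (res["p_raw"] > 0.9).all()

    def test_missing_sample_is_named(self, small_fixture):
        _, _, table, _, _ = small_fixture
        rel = normalize_relative(table)
        groups = SampleGroups("A", ("caseA_001", "ghost"), "B", ("caseB_001", "caseB_002"))
        with pytest.raises(UsageError, match="ghost"):
            compare_groups(rel, groups)

    def test_spiked_features_dominate_smallest_p(self, small_fixture, small_groups):
        _, _, table, _, truth = small_fixture
        res = compare_groups(normalize_relative(table), small_groups)
        top = set(res.index[: len(truth)])
        assert len(top & set(truth.index)) >= len(truth) - 1

    def test_sorted_by_adjusted_p(self, small_fixture, small_groups):
        _, _, table, _, _ = small_fixture
        res = compare_groups(normalize_relative(table), small_groups)
        assert list(res["p_adj"]) == sorted(res["p_adj"])

    def test_default_pseudocount_is_half_min_nonzero_mean(self):
        eps = default_pseudocount(np.array([0.0, 0.3]), np.array([0.1, 0.0]))
        assert eps == pytest.approx(0.05)


class TestFilter:
    def _results(self, **overrides):
        base = dict(level_name="genus", statistic=1.0, p_raw=0.01, p_adj=0.15,
                    fold_change=1.8, abs_fold_change=1.8, mean_rel_a=0.02,
                    mean_rel_b=0.01, test="mannwhitney", adjustment="bh")
        base.update(overrides)
        return pd.DataFrame([base], index=pd.Index(["f0"], name="feature_id"))

    def test_joint_retention(self):
        res = self._results()
        kept = filter_results(res, p_max=0.2, min_abs_fc=1.5, min_mean_rel=0.005)
        assert list(kept.index) == ["f0"]

    def test_identity_filter(self, small_fixture, small_groups):
        _, _, table, _, _ = small_fixture
        res = compare_groups(normalize_relative(table), small_groups)
        kept = filter_results(res, p_max=1.0, min_abs_fc=1.0, min_mean_rel=0.0)
        assert len(kept) == len(res)

    def test_huge_fold_change_empties_result(self):
        assert filter_results(self._results(), p_max=1.0, min_abs_fc=1e9).empty

    def test_p_filter_uses_adjusted_when_adjusted(self):
        res = self._results(p_raw=0.001, p_adj=0.5)
        assert filter_results(res, p_max=0.05).empty
        raw = self._results(p_raw=0.001, p_adj=0.5, adjustment="none")
        assert not filter_results(raw, p_max=0.05).empty

    @pytest.mark.parametrize("kwargs", [{"p_max": 0.0}, {"min_abs_fc": 0.5},
                                        {"min_mean_rel": 1.0}])
    def test_nonsense_thresholds_rejected(self, kwargs):
        with pytest.raises(UsageError):
            filter_results(self._results(), **kwargs)


class TestCorrelation:
    def _md(self, values, extra=None):
        df = pd.DataFrame({"BMI": values}, index=[f"s{i + 1}" for i in range(len(values))])
        types = {"BMI": "numerical"}
        if extra:
            df["nat"] = extra
            types["nat"] = "categorical"
        return SampleMetadata(df, types)

    def test_perfect_monotone(self):
        table = _rel_table([[0.1, 0.2, 0.3, 0.4], [0.9, 0.8, 0.7, 0.6]],
                           ["s1", "s2", "s3", "s4"])
        md = self._md([20.0, 25.0, 30.0, 35.0])
        res = correlate_with_metadata(table, md, "BMI", method="spearman")
        assert res.loc["f0", "coefficient"] == pytest.approx(1.0)
        assert res.loc["f1", "coefficient"] == pytest.approx(-1.0)

    def test_constant_feature_flagged_and_excluded(self):
        table = AbundanceTable(
            pd.DataFrame([[0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5]],
                         index=["f0", "f1"], columns=["s1", "s2", "s3", "s4"]),
            mode="relative", _strict=False)
        md = self._md([20.0, 25.0, 30.0, 35.0])
        res = correlate_with_metadata(table, md, "BMI")
        assert not res["available"].any()
        assert res["p_adj"].isna().all()

    def test_categorical_variable_rejected(self):
        table = _rel_table([[0.1, 0.2, 0.3]], ["s1", "s2", "s3"])
        md = self._md([1.0, 2.0, 3.0], extra=["a", "b", "c"])
        with pytest.raises(UsageError, match="categorical"):
            correlate_with_metadata(table, md, "nat")

    def test_missing_values_excluded_pairwise(self):
        table = _rel_table([[0.1, 0.2, 0.3, 0.4, 0.5], [0.9, 0.8, 0.7, 0.6, 0.5]],
                           [f"s{i + 1}" for i in range(5)])
        md = self._md([20.0, np.nan, 30.0, 35.0, 40.0])
        res = correlate_with_metadata(table, md, "BMI")
        assert res.loc["f0", "n"] == 4
        assert res.loc["f0", "coefficient"] == pytest.approx(1.0)
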