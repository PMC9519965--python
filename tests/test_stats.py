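"""Wilks-lambda MANOVA, univariate follow-ups, t, chi-square, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from l2speech.stats import (
    TwoGroupManova,
    anova_univariate,
    baseline_diagnostics,
    chi_square_independence,
    intercorrelation_check,
    manova_family,
    one_sample_t,
)

GROUPS36 = np.repeat(["active", "sham"], 18)


def brute_force_wilks(x, groups):
    """Independent oracle: explicit elementwise cross-product accumulation."""
    x = np.asarray(x, float)
    n, p = x.shape
    levels = sorted(set(groups))
    grand = x.mean(axis=0)
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for lvl in levels:
        xg = x[np.asarray(groups) == lvl]
        mg = xg.mean(axis=0)
        for i in range(p):
            for j in range(p):
                h[i, j] += len(xg) * (mg[i] - grand[i]) * (mg[j] - grand[j])
        for row in xg:
            for i in range(p):
                for j in range(p):
                    e[i, j] += (row[i] - mg[i]) * (row[j] - mg[j])
    lam = np.linalg.det(e) / np.linalg.det(e + h)
    df1, df2 = p, n - p - 1
    f = (df2 / df1) * (1 - lam) / lam
    return lam, f, float(sps.f.sf(f, df1, df2))


class TestManova:
    def test_identical_group_means_give_null_identity(self):
        base = np.random.default_rng(0).standard_normal((18, 3))
        x = np.vstack([base, base])  # both groups identical
        res = TwoGroupManova(x, GROUPS36).fit()
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)
        assert res.pvalue == pytest.approx(1.0)

    def test_single_variable_reduces_to_univariate_anova(self, rng):
        x = rng.standard_normal(36)
        res = TwoGroupManova(x, GROUPS36).fit()
        uni = anova_univariate(x, GROUPS36)
        assert res.f_stat == pytest.approx(uni.statistic, rel=1e-12)
        assert (res.df1, res.df2) == uni.df
        assert res.pvalue == pytest.approx(uni.pvalue, rel=1e-12)

    def test_agrees_with_brute_force_oracle_to_1e10(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal((36, 3)) + r.uniform(-1, 1, 3)
            res = TwoGroupManova(x, GROUPS36).fit()
            lam, f, p = brute_force_wilks(x, GROUPS36)
            assert res.wilks_lambda == pytest.approx(lam, abs=1e-10)
            assert res.f_stat == pytest.approx(f, abs=1e-10)
            assert res.pvalue == pytest.approx(p, abs=1e-10)

    def test_agrees_with_reference_library_to_1e8(self):
        from statsmodels.multivariate.manova import MANOVA

        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.standard_normal((36, 4))
            res = TwoGroupManova(x, GROUPS36).fit()
            df = pd.DataFrame(x, columns=[f"y{i}" for i in range(4)])
            df["g"] = GROUPS36
            tab = MANOVA.from_formula(
                "y0 + y1 + y2 + y3 ~ g", data=df
            ).mv_test().results["g"]["stat"]
            assert res.wilks_lambda == pytest.approx(
                tab.loc["Wilks' lambda", "Value"], abs=1e-8)
            assert res.f_stat == pytest.approx(
                tab.loc["Wilks' lambda", "F Value"], abs=1e-8)
            assert res.pvalue == pytest.approx(
                tab.loc["Wilks' lambda", "Pr > F"], abs=1e-8)

    def test_df_pattern_matches_two_group_design(self, rng):
        x = rng.standard_normal((36, 3))
        res = TwoGroupManova(x, GROUPS36).fit()
        assert (res.df1, res.df2) == (3, 32)
        x4 = rng.standard_normal((36, 4))
        res4 = TwoGroupManova(x4, GROUPS36).fit()
        assert (res4.df1, res4.df2) == (4, 31)

    def test_invariant_to_participant_ordering(self, rng):
        x = rng.standard_normal((36, 3))
        perm = rng.permutation(36)
        a = TwoGroupManova(x, GROUPS36).fit()
        b = TwoGroupManova(x[perm], GROUPS36[perm]).fit()
        assert a.wilks_lambda == pytest.approx(b.wilks_lambda, rel=1e-12)
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-12)

    def test_collinear_variables_rejected_with_diagnosis(self, rng):
        x = rng.standard_normal((36, 2))
        x = np.column_stack([x, x[:, 0]])  # exact duplicate
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            TwoGroupManova(x, GROUPS36).fit()

    def test_more_variables_than_group_members_rejected(self, rng):
        x = rng.standard_normal((8, 5))
        with pytest.raises(ValueError, match="more members"):
            TwoGroupManova(x, np.repeat(["a", "b"], 4))

    def test_summary_reports_lambda_f_and_followups(self, rng):
        res = TwoGroupManova(rng.standard_normal((36, 3)), GROUPS36).fit()
        s = res.summary()
        assert "Wilks' lambda" in s and "F(3,32)" in s
        assert len(res.univariate) == 3


class TestAnova:
    def test_hand_computed_example(self):
        # groups (1,2,3) vs (4,5,6): between SS = 3*(1.5^2)*2 = 13.5,
        # within SS = 2 + 2 = 4 on 4 df -> F = 13.5 / 1 = 13.5
        res = anova_univariate([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_equal_group_means_give_zero_f(self):
        res = anova_univariate([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0)

    def test_f_equals_t_squared(self, rng):
        x = rng.standard_normal(30)
        g = np.repeat(["a", "b"], 15)
        res = anova_univariate(x, g)
        t = sps.ttest_ind(x[g == "a"], x[g == "b"]).statistic
        assert res.statistic == pytest.approx(t**2, abs=1e-10)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_univariate([1, 1, 2, 2], ["a", "a", "b", "b"])


class TestOneSampleT:
    def test_all_zero_scores_are_uninformative(self):
        res = one_sample_t([0.0, 0.0, 0.0, 0.0])
        assert res.statistic == 0.0
        assert res.pvalue == 0.5

    def test_hand_computed_example(self):
        res = one_sample_t([1.0, 1.0, 1.0, 3.0])
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (3,)

    def test_negation_maps_p_to_complement(self, rng):
        x = rng.standard_normal(18) + 0.4
        a = one_sample_t(x)
        b = one_sample_t(-x)
        assert a.pvalue + b.pvalue == pytest.approx(1.0)

    def test_zero_variance_nonzero_effect_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_t([2.0, 2.0, 2.0])


class TestChiSquare:
    def test_blinding_guess_table_reproduces_printed_value(self):
        res = chi_square_independence([[11, 7], [9, 9]])
        assert round(res.statistic, 2) == 0.45
        assert res.df == (1,)
        assert res.pvalue == pytest.approx(0.50, abs=0.01)

    def test_exact_independence_gives_zero(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)

    def test_row_swap_invariance(self):
        a = chi_square_independence([[11, 7], [9, 9]])
        b = chi_square_independence([[9, 9], [11, 7]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [5, 5]])


class TestPrescreen:
    def test_duplicated_column_passes(self, rng):
        x = rng.standard_normal((36, 1))
        passed, r, _ = intercorrelation_check(np.column_stack([x, x]))
        assert passed
        assert r[0, 1] == pytest.approx(1.0)

    def test_independent_columns_typically_fail(self):
        fails = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((36, 3))
            passed, _, _ = intercorrelation_check(x)
            fails += not passed
        assert fails >= 18  # independent data rarely clears |r| > 0.30 pairwise

    def test_matrix_symmetric_unit_diagonal(self, rng):
        _, r, _ = intercorrelation_check(rng.standard_normal((20, 4)))
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_constant_variable_fails_with_diagnostic(self, rng):
        x = rng.standard_normal((20, 2))
        x[:, 1] = 7.0
        passed, _, notes = intercorrelation_check(x)
        assert not passed
        assert any("constant" in n for n in notes)


class TestBaselineDiagnostics:
    @staticmethod
    def _scores(pre_a, pre_b, post_a=None, post_b=None):
        rows = []
        post_a = pre_a if post_a is None else post_a
        post_b = pre_b if post_b is None else post_b
        for i, (pre, post) in enumerate(zip(pre_a, post_a)):
            rows.append((f"a{i}", "active", "x", pre, post, post - pre,
                         abs(post - pre)))
        for i, (pre, post) in enumerate(zip(pre_b, post_b)):
            rows.append((f"s{i}", "sham", "x", pre, post, post - pre,
                         abs(post - pre)))
        return pd.DataFrame(
            rows, columns=["participant", "group", "variable", "pre", "post",
                           "difference", "distance"]
        )

    def test_identical_baselines_give_zero_point_biserial(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        d = baseline_diagnostics(self._scores(vals, vals))
        assert d.point_biserial_r.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_post_equals_pre_gives_unit_reliability(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        d = baseline_diagnostics(self._scores(a, b))
        assert d.pre_post_r.iloc[0] == pytest.approx(1.0)

    def test_injected_baseline_imbalance_recovered(self, rng):
        # group means 0 vs 1 with unit sd: point-biserial approx 0.45
        a = rng.normal(1.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        d = baseline_diagnostics(self._scores(a, b))
        expected = 0.5 / np.sqrt(0.5**2 + 1.0)  # mean gap over total sd
        assert abs(d.point_biserial_r.iloc[0]) == pytest.approx(expected, abs=0.08)


class TestManovaFamily:
    def test_family_runs_and_warns_on_uncorrelated_dvs(self, rng):
        rows = []
        for i in range(36):
            g = "active" if i < 18 else "sham"
            for v in ("a", "b"):
                rows.append((f"p{i}", g, v, 0.0, 0.0,
                             rng.standard_normal(), 0.0))
        scores = pd.DataFrame(
            rows, columns=["participant", "group", "variable", "pre", "post",
                           "difference", "distance"]
        )
        with pytest.warns(UserWarning, match="inter-correlated"):
            out = manova_family(scores, ["a", "b"])
        assert 0.0 <= out["manova"]["p"] <= 1.0
        assert set(out["one_sample_t"]) == {"active", "sham"}
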