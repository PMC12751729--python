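"""Tests of group-comparison and association statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from scdeeg.stats import (
    ancova_partial_eta2,
    chi_square_test,
    cohens_d_from_summary,
    fdr_bh,
    independent_t_and_d,
    normality_check,
    paired_t_and_d,
    partial_correlation_bootstrap,
)


class TestNormalityCheck:
    def test_gaussian_passes(self, rng):
        assert normality_check(rng.standard_normal(200))

    def test_heavy_skew_fails(self, rng):
        assert not normality_check(rng.lognormal(0, 2.0, size=500))

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_check(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            normality_check(np.ones(10))


class TestCohensD:
    def test_summary_reproduces_published_followup_effects(self):
        """Frozen cognitive-score summaries reproduce known effect sizes."""
        # (mean1, sd1, n1, mean2, sd2, n2) -> expected |d| to two decimals
        cases = [
            ((40.99, 27.65, 26, 63.72, 27.09, 26), 0.83),
            ((60.38, 26.59, 26, 81.07, 21.25, 26), 0.86),
        ]
        for (m1, s1, n1, m2, s2, n2), expected in cases:
            d = cohens_d_from_summary(m1, s1, n1, m2, s2, n2)
            assert d == pytest.approx(expected, abs=0.01)

    def test_sign_convention_group2_larger_is_positive(self):
        assert cohens_d_from_summary(0.0, 1.0, 10, 1.0, 1.0, 10) > 0
        assert cohens_d_from_summary(1.0, 1.0, 10, 0.0, 1.0, 10) < 0

    def test_unit_case(self):
        # means differ by exactly one pooled SD
        assert cohens_d_from_summary(0.0, 1.0, 50, 1.0, 1.0, 50) == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_summary(0.0, 0.0, 5, 1.0, 0.0, 5)


class TestIndependentT:
    def test_matches_scipy_pooled_t(self, rng):
        x1 = rng.standard_normal(24)
        x2 = 0.5 + rng.standard_normal(82)
        res = independent_t_and_d(x1, x2)
        t_ref, p_ref = sps.ttest_ind(x1, x2, equal_var=True)
        assert res.statistic == pytest.approx(t_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_summary_and_sample_inputs_agree(self, rng):
        x1, x2 = rng.standard_normal(20), 1 + rng.standard_normal(30)
        a = independent_t_and_d(x1, x2)
        b = independent_t_and_d(
            (x1.mean(), x1.std(ddof=1), 20), (x2.mean(), x2.std(ddof=1), 30)
        )
        assert a.statistic == pytest.approx(b.statistic)
        assert a.effect_size == pytest.approx(b.effect_size)

    def test_ci_formula(self):
        res = independent_t_and_d((0.0, 1.0, 26), (0.83, 1.0, 26))
        d = res.effect_size
        se = np.sqrt((26 + 26) / (26 * 26) + d**2 / (2 * 52))
        assert res.ci95 == pytest.approx((d - 1.96 * se, d + 1.96 * se))

    def test_known_ci_lower_bound(self):
        """d ~ 0.86 at n = 24 vs 82 has CI lower bound near 0.38-0.39."""
        res = independent_t_and_d((30.69, 26.00, 24), (52.21, 24.91, 82))
        assert res.effect_size == pytest.approx(0.86, abs=0.01)
        assert 0.37 <= res.ci95[0] <= 0.40

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_property_sign_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.standard_normal(12), rng.standard_normal(15)
        a = independent_t_and_d(x1, x2)
        b = independent_t_and_d(x2, x1)
        assert a.effect_size == pytest.approx(-b.effect_size, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestPairedT:
    def test_matches_scipy(self, rng):
        pre = rng.standard_normal(26)
        post = pre + 0.5 + 0.3 * rng.standard_normal(26)
        res = paired_t_and_d(pre, post)
        t_ref, p_ref = sps.ttest_rel(pre, post)
        assert res.statistic == pytest.approx(t_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_d_is_mean_over_sd_of_differences(self, rng):
        pre = rng.standard_normal(30)
        post = pre - 1.0 + 0.2 * rng.standard_normal(30)
        res = paired_t_and_d(pre, post)
        diff = pre - post
        assert res.effect_size == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_and_d(np.zeros(5), np.zeros(6))


class TestChiSquare:
    def test_known_2x2_value(self):
        """APOE4 carrier table 12/24 vs 9/82: chi2 = 17.8 to one decimal."""
        table = np.array([[12, 12], [9, 73]])
        res = chi_square_test(table)
        assert res.statistic == pytest.approx(17.798, abs=0.001)
        assert res.p_value < 1e-4

    def test_matches_scipy_no_continuity_correction(self, rng):
        table = rng.integers(5, 40, size=(2, 2))
        res = chi_square_test(table)
        chi2, p, *_ = sps.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test(np.array([[0, 0], [5, 7]]))


class TestAncova:
    @staticmethod
    def _data(n1=24, n2=82, effect=0.5, seed=0):
        rng = np.random.default_rng(seed)
        group = np.array(["A_plus"] * n1 + ["A_minus"] * n2)
        age = np.concatenate(
            [rng.normal(73.4, 5.6, n1), rng.normal(69.8, 6.1, n2)]
        )
        y = 0.05 * age + effect * (group == "A_plus") + rng.standard_normal(n1 + n2)
        return y, group, age

    def test_matches_statsmodels_ols_anova(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        y, group, age = self._data()
        res = ancova_partial_eta2(y, group, age)
        df = pd.DataFrame({"y": y, "g": group, "age": age})
        fit = ols("y ~ C(g) + age", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.statistic == pytest.approx(tab.loc["C(g)", "F"], rel=1e-10)
        assert res.p_value == pytest.approx(tab.loc["C(g)", "PR(>F)"], rel=1e-8)
        eta_ref = tab.loc["C(g)", "sum_sq"] / (
            tab.loc["C(g)", "sum_sq"] + tab.loc["Residual", "sum_sq"]
        )
        assert res.effect_size == pytest.approx(eta_ref, rel=1e-10)

    def test_null_effect_gives_small_eta(self):
        y, group, age = self._data(effect=0.0, seed=3)
        res = ancova_partial_eta2(y, group, age)
        assert res.effect_size < 0.05

    def test_group_count_validation(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="2 groups"):
            ancova_partial_eta2(y, np.array(["a"] * 10), y)

    def test_collinear_covariate_rejected(self):
        group = np.array(["a"] * 5 + ["b"] * 5)
        cov = (group == "a").astype(float)
        with pytest.raises(ValueError, match="collinear"):
            ancova_partial_eta2(np.arange(10.0), group, cov)


class TestPartialCorrelation:
    @staticmethod
    def _data(n=106, r_target=-0.4, seed=0):
        rng = np.random.default_rng(seed)
        cov = rng.normal(70, 6, n)
        x = 0.3 * cov + rng.standard_normal(n)
        y = 0.2 * cov + r_target * (x - 0.3 * cov) + np.sqrt(
            1 - r_target**2
        ) * rng.standard_normal(n)
        return x, y, cov

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        x, y, cov = self._data()
        res = partial_correlation_bootstrap(x, y, cov, n_boot=100, seed=1)
        df = pd.DataFrame({"x": x, "y": y, "c": cov})
        ref = pg.partial_corr(df, x="x", y="y", covar="c")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_bootstrap_ci_brackets_r_and_is_deterministic(self):
        x, y, cov = self._data()
        a = partial_correlation_bootstrap(x, y, cov, n_boot=500, seed=7)
        b = partial_correlation_bootstrap(x, y, cov, n_boot=500, seed=7)
        assert a.ci95 == b.ci95
        assert a.ci95[0] < a.r < a.ci95[1]

    def test_removes_covariate_driven_association(self, rng):
        """x and y both driven by cov only: partial r near zero."""
        n = 300
        cov = rng.standard_normal(n)
        x = cov + 0.5 * rng.standard_normal(n)
        y = cov + 0.5 * rng.standard_normal(n)
        res = partial_correlation_bootstrap(x, y, cov, n_boot=100, seed=0)
        raw_r = np.corrcoef(x, y)[0, 1]
        assert raw_r > 0.5
        assert abs(res.r) < 0.2

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation_bootstrap(
                np.arange(4.0), np.arange(4.0), np.arange(4.0)
            )


class TestFDR:
    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=50)
        from statsmodels.stats.multitest import multipletests

        reject_ref, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(fdr_bh(p), reject_ref)

    def test_null_uniform_rarely_rejects(self, rng):
        p = rng.uniform(size=1000)
        assert fdr_bh(p).mean() < 0.02
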