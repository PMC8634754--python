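"""Group-comparison tests, regression, and the cohort summary table."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dtialps import (
    CohortSimParams,
    chi_square_2x2,
    linear_regression,
    one_way_anova_posthoc,
    simulate_cohort,
    summarize_cohort,
    t_test,
    t_test_from_summary,
)


def welch_oracle(a, b):
    """Closed-form Welch test written out from first principles."""
    n1, n2 = len(a), len(b)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(a) - np.mean(b)) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def chi2_oracle(table):
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    stat = np.sum((table - expected) ** 2 / expected)
    return stat, 1 - sps.chi2.cdf(stat, 1)


def anova_oracle(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, sps.f.sf(F, dfb, dfw)


def ols_oracle(X, y):
    """Normal equations, assembled and inverted explicitly."""
    Xd = np.column_stack([np.ones(len(X)), X])
    return np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y


class TestTTest:
    def test_identical_summaries(self):
        t, df, p = t_test_from_summary(10, 5.0, 1.0, 12, 5.0, 1.0)
        assert t == 0.0 and p == 1.0

    def test_printed_age_summaries_round_to_expected_p(self):
        _, _, p = t_test_from_summary(36, 62.00, 6.24, 71, 64.68, 8.12, "welch")
        assert round(p, 3) == 0.062

    def test_pooled_alps_summaries(self):
        t, df, p = t_test_from_summary(36, 1.53, 0.16, 71, 1.44, 0.16, "pooled")
        assert t == pytest.approx(2.75, abs=0.01)
        assert p == pytest.approx(0.007, abs=0.0005)
        assert df == 105

    def test_raw_and_summary_paths_coincide(self):
        rng = np.random.default_rng(0)
        for variant in ("welch", "pooled"):
            a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1.5, 31)
            t1, df1, p1 = t_test(a, b, variant)
            t2, df2, p2 = t_test_from_summary(
                len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1), variant
            )
            assert abs(t1 - t2) < 1e-12 and abs(p1 - p2) < 1e-12 and df1 == df2

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(0.3, 2, rng.integers(5, 40))
            t, df, p = t_test(a, b, "welch")
            to, dfo, po = welch_oracle(a, b)
            assert abs(t - to) < 1e-10 and abs(df - dfo) < 1e-8 and abs(p - po) < 1e-10

    def test_welch_df_bounded_by_pooled_df(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 14), rng.normal(0, 3, 9)
        _, df, _ = t_test(a, b, "welch")
        assert df <= len(a) + len(b) - 2

    def test_power_against_calibrated_group_separation(self):
        """At d ≈ 0.56 with n = (36, 71), rejection rate lands in [0.60, 0.90]."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            nc = rng.normal(1.53, 0.16, 36)
            pdg = rng.normal(1.44, 0.16, 71)
            if t_test(nc, pdg)[2] < 0.05:
                rejections += 1
        assert 0.60 <= rejections / reps <= 0.90

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1, 0, 1, 10, 0, 1)
        with pytest.raises(ValueError):
            t_test_from_summary(5, 0, 0, 10, 0, 1)
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_printed_sex_table(self):
        stat, df, p = chi_square_2x2([[18, 18], [31, 40]])
        assert df == 1
        assert round(p, 3) == 0.534

    def test_equal_proportions(self):
        stat, _, p = chi_square_2x2([[10, 10], [20, 20]])
        assert stat == 0.0 and p == 1.0

    def test_matches_expected_count_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            table = rng.integers(1, 60, size=(2, 2))
            stat, _, p = chi_square_2x2(table)
            so, po = chi2_oracle(table)
            assert abs(stat - so) < 1e-10 and abs(p - po) < 1e-10

    def test_yates_reduces_statistic(self):
        plain = chi_square_2x2([[18, 18], [31, 40]], "none")[0]
        yates = chi_square_2x2([[18, 18], [31, 40]], "yates")[0]
        assert yates < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        F, dfs, p, pairwise = one_way_anova_posthoc([g, g, g])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert len(pairwise) == 3

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.3, 1.0, 20 + i) for i in range(3)]
        F, _, p, _ = one_way_anova_posthoc(groups)
        Fo, po = anova_oracle(groups)
        assert abs(F - Fo) < 1e-10 and abs(p - po) < 1e-10

    def test_posthoc_detects_largest_separation_more_often(self):
        """NC-vs-late significant more often than NC-vs-early at Table-1 effect sizes."""
        rng = np.random.default_rng(123)
        hits_late, hits_early = 0, 0
        for _ in range(500):
            nc = rng.normal(1.53, 0.16, 36)
            epd = rng.normal(1.46, 0.15, 35)
            lpd = rng.normal(1.42, 0.18, 36)
            _, _, _, pw = one_way_anova_posthoc(
                [nc, epd, lpd], labels=["NC", "ePD", "lPD"]
            )
            pw = pw.set_index(["group_a", "group_b"])["p"]
            hits_late += pw[("NC", "lPD")] < 0.05
            hits_early += pw[("NC", "ePD")] < 0.05
        assert hits_late > hits_early

    def test_lsd_less_conservative_than_tukey(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(i * 0.4, 1.0, 15) for i in range(3)]
        _, _, _, tukey = one_way_anova_posthoc(groups, posthoc="tukey")
        _, _, _, lsd = one_way_anova_posthoc(groups, posthoc="lsd")
        assert (lsd["p"] <= tukey["p"] + 1e-12).all()

    def test_two_groups_redirected_to_t_test(self):
        with pytest.raises(ValueError, match="t_test"):
            one_way_anova_posthoc([[1.0, 2.0], [3.0, 4.0]])


class TestLinearRegression:
    @staticmethod
    def _toy_cohort(n=200, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "group": "ePD",
                "age": rng.normal(64, 8, n),
                "mmse": rng.normal(28, 2, n),
                "sex": rng.choice(["M", "F"], n),
            }
        )
        df["alps"] = 1.5 + 0.02 * df["mmse"] - 0.005 * df["age"] + rng.normal(0, 0.05, n)
        return df

    def test_response_equal_to_covariate(self):
        df = self._toy_cohort()
        df["alps"] = df["mmse"]
        res = linear_regression(df, covariates=["mmse"])
        assert res.beta["mmse"] == pytest.approx(1.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        df = self._toy_cohort(seed=3)
        res = linear_regression(df, covariates=["age", "mmse"])
        beta = ols_oracle(df[["age", "mmse"]].to_numpy(), df["alps"].to_numpy())
        assert res.beta["const"] == pytest.approx(beta[0], abs=1e-10)
        assert res.beta["age"] == pytest.approx(beta[1], abs=1e-10)
        assert res.beta["mmse"] == pytest.approx(beta[2], abs=1e-10)

    def test_singular_design_names_collinear_columns(self):
        df = self._toy_cohort()
        df["age2"] = df["age"] * 2
        with pytest.raises(ValueError, match="singular|collinear"):
            linear_regression(df, covariates=["age", "age2"])

    def test_constant_covariate_rejected(self):
        df = self._toy_cohort()
        df["hy"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            linear_regression(df, covariates=["hy"])

    def test_missing_rows_dropped_and_counted(self):
        df = self._toy_cohort()
        df.loc[:9, "mmse"] = np.nan
        res = linear_regression(df, covariates=["mmse"])
        assert res.n_dropped == 10
        assert res.n == len(df) - 10

    def test_sex_coded_as_indicator(self):
        rng = np.random.default_rng(1)
        df = self._toy_cohort(seed=1)
        df["alps"] = np.where(df["sex"] == "M", 2.0, 1.0) + rng.normal(0, 1e-6, len(df))
        res = linear_regression(df, covariates=["sex"])
        assert res.beta["sex"] == pytest.approx(1.0, abs=1e-4)


class TestSummarizeCohort:
    def test_contains_expected_rows(self):
        df = simulate_cohort(CohortSimParams(seed=2))
        table = summarize_cohort(df)
        variables = set(table["variable"])
        for needed in ("age", "sex (M/F)", "mmse", "education_y", "alps",
                       "duration_y", "updrs3", "updrs_total", "epvs", "pvwmh"):
            assert needed in variables
        assert table["p_epd_vs_lpd"].dropna().between(0, 1).all()
        assert table["p_nc_vs_pd"].dropna().between(0, 1).all()

    def test_single_group_rejected(self):
        df = simulate_cohort(CohortSimParams(seed=2))
        with pytest.raises(ValueError):
            summarize_cohort(df[df.group == "NC"])

    def test_missing_columns_rejected(self):
        df = simulate_cohort(CohortSimParams(seed=2)).drop(columns=["alps"])
        with pytest.raises(ValueError, match="missing"):
            summarize_cohort(df)
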