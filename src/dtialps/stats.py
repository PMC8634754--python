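"""Cohort statistics: group comparisons and ALPS-vs-covariate regressions.

Mirrors the analysis plan of clinical ALPS studies: two-sample t-tests and
chi-square tests between patients and controls, one-way ANOVA with post hoc
pairwise tests across the three groups, Wilcoxon rank-sum for the ordinal
imaging scores, and multivariate linear regression of the ALPS index on
clinical covariates within each patient subgroup. Test computations are
delegated to scipy/statsmodels; this module owns the summary-table shapes,
input validation and coding conventions (sex as a 0/1 indicator, no
multiple-testing correction, p < 0.05 reported as significant).
"""

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "t_test",
    "t_test_from_summary",
    "chi_square_2x2",
    "one_way_anova_posthoc",
    "RegressionResult",
    "linear_regression",
    "summarize_cohort",
]

CONDITION_NUMBER_WARN = 1e3


def _welch_df(v1, n1, v2, n2):
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def t_test_from_summary(n1, mean1, sd1, n2, mean2, sd2, variant="welch"):
    """Two-sided two-sample t-test from summary statistics.

    ``variant='welch'`` (default) uses the Satterthwaite approximation for the
    degrees of freedom; ``'pooled'`` assumes equal variances. Returns
    ``(t, df, p)``.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        df = _welch_df(sd1**2, n1, sd2**2, n2)
    return float(res.statistic), float(df), float(res.pvalue)


def t_test(values_a, values_b, variant="welch"):
    """Two-sided two-sample t-test on raw samples; returns ``(t, df, p)``.

    Agrees exactly with :func:`t_test_from_summary` on matching summaries.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    return t_test_from_summary(
        a.size, a.mean(), a.std(ddof=1), b.size, b.mean(), b.std(ddof=1), variant
    )


def chi_square_2x2(table, correction="none"):
    """Pearson chi-square test on a 2×2 contingency table; returns (χ², df, p).

    ``correction='yates'`` applies the continuity correction (subtract 0.5
    from each |O − E|). Margins must all be positive.
    """
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain nonnegative integer counts")
    t = t.astype(float)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be > 0")
    res = sps.chi2_contingency(t, correction=(correction == "yates"))
    return float(res.statistic), int(res.dof), float(res.pvalue)


def one_way_anova_posthoc(groups, posthoc="tukey", labels=None):
    """One-way ANOVA over ≥3 samples plus pairwise post hoc comparisons.

    Returns ``(F, (df_between, df_within), p, pairwise)`` where ``pairwise``
    is a DataFrame with columns group_a, group_b, diff, p. ``posthoc`` is
    Tukey's HSD (default) or Fisher's LSD (unadjusted pairwise t-tests on the
    pooled within-group variance).
    """
    if posthoc not in ("tukey", "lsd"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("need >= 3 groups; use t_test for two samples")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    N = sum(g.size for g in groups)
    F, p = sps.f_oneway(*groups)
    dfb, dfw = k - 1, N - k

    rows = []
    if posthoc == "tukey":
        res = sps.tukey_hsd(*groups)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    (labels[i], labels[j],
                     groups[i].mean() - groups[j].mean(),
                     float(res.pvalue[i, j]))
                )
    else:
        msw = sum(((g.size - 1) * g.var(ddof=1) for g in groups)) / dfw
        for i in range(k):
            for j in range(i + 1, k):
                diff = groups[i].mean() - groups[j].mean()
                se = np.sqrt(msw * (1 / groups[i].size + 1 / groups[j].size))
                tstat = diff / se
                rows.append(
                    (labels[i], labels[j], diff,
                     float(2 * sps.t.sf(abs(tstat), dfw)))
                )
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p"])
    return float(F), (dfb, dfw), float(p), pairwise


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a response on clinical covariates."""

    response: str
    covariates: tuple
    beta: dict
    se: dict
    t: dict
    p: dict
    n: int
    r_squared: float
    n_dropped: int
    condition_number: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "t": self.t, "p": self.p}
        )


def linear_regression(cohort: pd.DataFrame, response="alps", covariates=(),
                      subset=None) -> RegressionResult:
    """Multivariate OLS of ``response`` on ``covariates`` with an intercept.

    ``subset`` filters on the ``group`` column (e.g. ``'ePD'``). Sex is coded
    M=1, F=0. Rows with missing values in any used column are dropped (count
    reported). Raises on singular designs, warns on condition number > 1e3
    (e.g. motor-subscore vs total-score collinearity).
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    df = cohort
    if subset is not None:
        df = df[df["group"] == subset]
        if df.empty:
            raise ValueError(f"no rows in subset group {subset!r}")
    cols = [response] + covariates
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    work = df[cols].copy()
    if "sex" in work.columns:
        work["sex"] = work["sex"].map({"M": 1, "F": 0, 1: 1, 0: 0})
    work = work.apply(pd.to_numeric)
    n_before = len(work)
    work = work.dropna()
    n_dropped = n_before - len(work)
    n = len(work)
    if n <= len(covariates) + 1:
        raise ValueError(f"n = {n} too small for {len(covariates)} covariates")
    constant = [c for c in covariates if work[c].nunique() == 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    X = sm.add_constant(work[covariates])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = work[covariates].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"singular design matrix; most collinear columns: {worst}"
        )
    fit = sm.OLS(work[response], X).fit()
    cond = float(np.linalg.cond(X.to_numpy()))
    if cond > CONDITION_NUMBER_WARN:
        warnings.warn(
            f"ill-conditioned design (condition number {cond:.3g}); "
            "coefficient estimates may be unstable", stacklevel=2
        )
    names = ["const"] + covariates
    return RegressionResult(
        response=response,
        covariates=tuple(covariates),
        beta={k: float(fit.params[k]) for k in names},
        se={k: float(fit.bse[k]) for k in names},
        t={k: float(fit.tvalues[k]) for k in names},
        p={k: float(fit.pvalues[k]) for k in names},
        n=n,
        r_squared=float(fit.rsquared),
        n_dropped=n_dropped,
        condition_number=cond,
    )


def _mean_sd(x):
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return "NA"
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _median_range(x):
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return "NA"
    return f"{np.median(x):g} ({x.min():g}–{x.max():g})"


def _ranksum_p(a, b):
    a = np.asarray(a, dtype=float); a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float); b = b[~np.isnan(b)]
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def summarize_cohort(cohort: pd.DataFrame, ttest_variant="welch") -> pd.DataFrame:
    """Demographics/clinical summary with NC-vs-PD and early-vs-late tests.

    One row per variable: group summaries (mean ± SD, M/F counts, or median
    (range) for the ordinal imaging scores), the test used, and p-values to 3
    decimals for controls vs all patients and early vs late patients.
    """
    required = {"group", "age", "sex", "mmse", "education_y", "alps"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    groups = set(cohort["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    nc = cohort[cohort["group"] == "NC"]
    epd = cohort[cohort["group"] == "ePD"]
    lpd = cohort[cohort["group"] == "lPD"]
    pdall = cohort[cohort["group"].isin(["ePD", "lPD"])]
    if nc.empty or epd.empty or lpd.empty:
        raise ValueError("expected the three groups NC, ePD, lPD")

    def t_p(a, b):
        return t_test(a, b, variant=ttest_variant)[2]

    rows = []

    def add(var, summ, test, p1, p2):
        rows.append({
            "variable": var,
            "nc": summ(nc) if var not in _PD_ONLY else "NA",
            "pd": summ(pdall),
            "p_nc_vs_pd": round(p1, 3) if p1 is not None else np.nan,
            "epd": summ(epd),
            "lpd": summ(lpd),
            "p_epd_vs_lpd": round(p2, 3) if p2 is not None else np.nan,
            "test": test,
        })

    _PD_ONLY = {"duration_y", "updrs1", "updrs2", "updrs3", "updrs4", "updrs5",
                "updrs_total", "epvs", "pvwmh", "hy"}

    for var in ("age", "mmse", "education_y", "alps"):
        add(var, lambda d, v=var: _mean_sd(d[v]),
            f"t ({ttest_variant})",
            t_p(nc[var], pdall[var]), t_p(epd[var], lpd[var]))

    def sex_summ(d):
        m = int((d["sex"] == "M").sum())
        return f"{m}/{len(d) - m}"

    def sex_table(a, b):
        return [[int((a["sex"] == "M").sum()), int((a["sex"] == "F").sum())],
                [int((b["sex"] == "M").sum()), int((b["sex"] == "F").sum())]]

    rows.append({
        "variable": "sex (M/F)", "nc": sex_summ(nc), "pd": sex_summ(pdall),
        "p_nc_vs_pd": round(chi_square_2x2(sex_table(nc, pdall))[2], 3),
        "epd": sex_summ(epd), "lpd": sex_summ(lpd),
        "p_epd_vs_lpd": round(chi_square_2x2(sex_table(epd, lpd))[2], 3),
        "test": "chi-square",
    })

    for var in ("duration_y", "updrs1", "updrs2", "updrs3", "updrs4", "updrs5",
                "updrs_total"):
        if var in cohort.columns:
            add(var, lambda d, v=var: _mean_sd(d[v]), f"t ({ttest_variant})",
                None, t_p(epd[var], lpd[var]))

    for var in ("epvs", "pvwmh"):
        if var in cohort.columns:
            add(var, lambda d, v=var: _median_range(d[v]), "rank-sum",
                None, _ranksum_p(epd[var], lpd[var]))

    return pd.DataFrame(rows)
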