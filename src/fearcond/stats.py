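"""Group-comparison statistics for the conditioning analyses.

Standard procedures (Welch/Student/paired t, chi-square, one-way ANOVA,
OLS with HC3 covariance, VIF, Holm) are thin wrappers over scipy and
statsmodels. Procedures without an established implementation are coded
from their formulas: Yuen's trimmed-means t with Wilcox's explanatory
measure of effect size xi, Cohen's d with a normal-approximation CI, the
2 (group) x 2 (CS type) split-plot ANOVA, and the effect-size conversions
used to compare exposure operationalizations on a common |d| scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "GroupComparisonResult",
    "welch_t",
    "welch_t_from_stats",
    "student_t_ind",
    "paired_t",
    "cohens_d",
    "cohens_d_from_stats",
    "ci_cohens_d",
    "chi_square_gof",
    "chi_square_2x2",
    "one_way_anova",
    "mixed_anova_2x2",
    "yuen_t",
    "trimmed_mean",
    "winsorized_variance",
    "ols_hc3",
    "vif",
    "holm_correct",
    "levene_median",
    "effect_to_abs_d",
    "compare_to_main_ci",
]

ALPHA = 0.05  # a priori two-tailed significance level used throughout


@dataclass
class GroupComparisonResult:
    """One statistical test: statistic, df, p and an effect size with CI."""

    method: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None
    effect_label: str | None = None
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def to_row(self) -> dict:
        lo, hi = self.ci if self.ci is not None else (np.nan, np.nan)
        df = self.df
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": df if np.isscalar(df) else f"{df[0]:g},{df[1]:g}",
            "p": self.p,
            "effect_size": np.nan if self.effect_size is None else self.effect_size,
            "effect_label": self.effect_label or "",
            "ci_lower": lo,
            "ci_upper": hi,
        }


def _as_clean(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a[np.isfinite(a)]


# --------------------------------------------------------------------------
# t-family
# --------------------------------------------------------------------------

def welch_t(a, b) -> GroupComparisonResult:
    """Welch's unequal-variance two-sample t-test (two-tailed)."""
    a, b = _as_clean(a), _as_clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("statistic undefined: both groups constant and equal")
    res = sps.ttest_ind(a, b, equal_var=False)
    d = cohens_d(a, b)
    return GroupComparisonResult(
        method="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        effect_size=d,
        effect_label="cohens_d",
        ci=ci_cohens_d(d, len(a), len(b)),
    )


def welch_t_from_stats(mean1, sd1, n1, mean2, sd2, n2) -> GroupComparisonResult:
    """Welch's t from summary statistics (means, SDs, group sizes)."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = math.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    d = cohens_d_from_stats(mean1, sd1, n1, mean2, sd2, n2)
    return GroupComparisonResult(
        method="welch_t",
        statistic=t,
        df=df,
        p=p,
        effect_size=d,
        effect_label="cohens_d",
        ci=ci_cohens_d(d, n1, n2),
    )


def student_t_ind(a, b) -> GroupComparisonResult:
    """Classical pooled-variance independent-samples t-test."""
    a, b = _as_clean(a), _as_clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("student_t_ind requires n >= 2 per group")
    res = sps.ttest_ind(a, b, equal_var=True)
    d = cohens_d(a, b)
    return GroupComparisonResult(
        method="student_t",
        statistic=float(res.statistic),
        df=float(len(a) + len(b) - 2),
        p=float(res.pvalue),
        effect_size=d,
        effect_label="cohens_d",
        ci=ci_cohens_d(d, len(a), len(b)),
    )


def paired_t(a, b) -> GroupComparisonResult:
    """Two-tailed paired-samples t-test; effect size d_z on the differences."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired_t requires two equal-length samples, n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        # identical pairs: no evidence of a difference
        stat, p, dz = (0.0, 1.0, 0.0) if diff.mean() == 0 else (np.inf, 0.0, np.inf)
    else:
        res = sps.ttest_rel(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        dz = float(diff.mean() / sd)
    return GroupComparisonResult(
        method="paired_t",
        statistic=stat,
        df=float(len(a) - 1),
        p=p,
        effect_size=dz,
        effect_label="cohens_dz",
    )


# --------------------------------------------------------------------------
# Cohen's d
# --------------------------------------------------------------------------

def cohens_d(a, b) -> float:
    """Pooled-SD Cohen's d for two independent samples (mean_a - mean_b)."""
    a, b = _as_clean(a), _as_clean(b)
    return cohens_d_from_stats(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def cohens_d_from_stats(mean1, sd1, n1, mean2, sd2, n2) -> float:
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("Cohen's d undefined: pooled SD is zero")
    return (mean1 - mean2) / pooled


def ci_cohens_d(d: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for d: d +- z * sqrt((n1+n2)/(n1 n2) + d^2/(2(n1+n2)))."""
    z = sps.norm.ppf(0.5 + level / 2)
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return (d - z * se, d + z * se)


# --------------------------------------------------------------------------
# chi-square
# --------------------------------------------------------------------------

def chi_square_gof(observed: Sequence[float], expected: Sequence[float] | None = None) -> GroupComparisonResult:
    """Goodness-of-fit chi-square; expected defaults to a uniform split."""
    obs = np.asarray(observed, float)
    if expected is None:
        expected = np.full_like(obs, obs.sum() / len(obs))
    exp = np.asarray(expected, float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    stat, p = sps.chisquare(obs, exp)
    return GroupComparisonResult(
        method="chi2_gof", statistic=float(stat), df=float(len(obs) - 1), p=float(p)
    )


def chi_square_2x2(table, correction: bool = True) -> GroupComparisonResult:
    """2x2 independence chi-square, Yates continuity correction by default."""
    tab = np.asarray(table, float)
    if tab.shape != (2, 2):
        raise ValueError("chi_square_2x2 expects a 2x2 table")
    res = sps.chi2_contingency(tab, correction=correction)
    return GroupComparisonResult(
        method="chi2_2x2", statistic=float(res.statistic), df=float(res.dof), p=float(res.pvalue)
    )


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

def one_way_anova(*groups) -> GroupComparisonResult:
    """Classical one-way between-subjects ANOVA with eta-squared."""
    gs = [_as_clean(g) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("one_way_anova requires >= 2 groups with n >= 2 each")
    stat, p = sps.f_oneway(*gs)
    k = len(gs)
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    sst = float(np.sum((np.concatenate(gs) - grand) ** 2))
    eta2 = ssb / sst if sst > 0 else 0.0
    return GroupComparisonResult(
        method="one_way_anova",
        statistic=float(stat),
        df=(float(k - 1), float(n - k)),
        p=float(p),
        effect_size=float(eta2),
        effect_label="eta2",
    )


def mixed_anova_2x2(y11, y12, y21, y22) -> dict[str, GroupComparisonResult]:
    """Split-plot ANOVA: 2 groups (between) x 2 within-subject levels.

    ``yjk`` is the vector of responses of group j at within-level k;
    (y11, y12) and (y21, y22) are paired within participants. Returns the
    group, within and interaction effects with partial eta-squared. SS are
    computed from the classical split-plot decomposition.
    """
    y11, y12 = np.asarray(y11, float), np.asarray(y12, float)
    y21, y22 = np.asarray(y21, float), np.asarray(y22, float)
    if y11.shape != y12.shape or y21.shape != y22.shape:
        raise ValueError("within-subject levels must pair up per participant")
    n1, n2 = len(y11), len(y21)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 participants")
    data = np.concatenate([np.stack([y11, y12], 1), np.stack([y21, y22], 1)])
    group = np.r_[np.zeros(n1, int), np.ones(n2, int)]
    n = n1 + n2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    group_means = np.array([data[group == j].mean() for j in (0, 1)])
    within_means = data.mean(axis=0)
    cell_means = np.array([[data[group == j, k].mean() for k in (0, 1)] for j in (0, 1)])
    ns = np.array([n1, n2], float)

    ss_group = float(2 * np.sum(ns * (group_means - grand) ** 2))
    ss_subj = float(2 * np.sum((subj_means - group_means[group]) ** 2))
    ss_within = float(n * np.sum((within_means - grand) ** 2))
    ss_inter = float(
        np.sum(
            ns[:, None]
            * (cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2
        )
    )
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = ss_total - ss_group - ss_subj - ss_within - ss_inter

    df_group, df_subj, df_w, df_err = 1.0, float(n - 2), 1.0, float(n - 2)
    out: dict[str, GroupComparisonResult] = {}
    for name, ss, dfn, ss_e, dfe in [
        ("group", ss_group, df_group, ss_subj, df_subj),
        ("within", ss_within, df_w, ss_err, df_err),
        ("interaction", ss_inter, df_w, ss_err, df_err),
    ]:
        if ss_e <= 0:
            out[name] = GroupComparisonResult(
                method=f"mixed_anova_{name}", statistic=np.nan, df=(dfn, dfe), p=np.nan,
                effect_size=np.nan, effect_label="partial_eta2",
                extra={"ss": ss, "ss_error": ss_e, "degenerate": True},
            )
            continue
        f = (ss / dfn) / (ss_e / dfe)
        p = float(sps.f.sf(f, dfn, dfe))
        out[name] = GroupComparisonResult(
            method=f"mixed_anova_{name}",
            statistic=float(f),
            df=(dfn, dfe),
            p=p,
            effect_size=float(ss / (ss + ss_e)),
            effect_label="partial_eta2",
            extra={"ss": ss, "ss_error": ss_e, "ss_total": ss_total},
        )
    return out


# --------------------------------------------------------------------------
# robust statistics (hand-implemented)
# --------------------------------------------------------------------------

def trimmed_mean(x, trim: float) -> float:
    """Symmetric trimmed mean; ``trim`` is the proportion cut from each tail."""
    return float(sps.trim_mean(np.asarray(x, float), trim))


def winsorized_variance(x, trim: float) -> float:
    """Sample variance after replacing each tail's trim-fraction with the cut points."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    g = int(np.floor(trim * n))
    w = x.copy()
    w[:g] = x[g]
    w[n - g:] = x[n - g - 1]
    return float(np.var(w, ddof=1))


def _winvar_normal(trim: float) -> float:
    """Winsorized variance of a standard normal at the given trim proportion."""
    if trim == 0:
        return 1.0
    q = sps.norm.ppf(1 - trim)
    middle = (1 - 2 * trim) - 2 * q * sps.norm.pdf(q)
    return float(middle + 2 * trim * q**2)


def yuen_t(a, b, trim: float = 0.2) -> GroupComparisonResult:
    """Yuen's trimmed-means t-test with the explanatory effect size xi.

    The statistic compares the two trimmed means using standard errors built
    from Winsorized variances; at ``trim=0`` it reduces exactly to Welch's t.
    xi is the square root of the ratio of the variance explained by the group
    trimmed means to a robust estimate of the total variance (the pooled
    Winsorized variance rescaled by its value under a standard normal), with
    benchmarks 0.10 / 0.30 / 0.50 for small / medium / large.
    """
    if not 0 <= trim <= 0.25:
        raise ValueError("trim must be in [0, 0.25]")
    a, b = _as_clean(a), _as_clean(b)
    n1, n2 = len(a), len(b)
    g1, g2 = int(np.floor(trim * n1)), int(np.floor(trim * n2))
    h1, h2 = n1 - 2 * g1, n2 - 2 * g2
    if h1 < 2 or h2 < 2:
        raise ValueError("too few observations remain after trimming")
    tm1, tm2 = trimmed_mean(a, trim), trimmed_mean(b, trim)
    d1 = (n1 - 1) * winsorized_variance(a, trim) / (h1 * (h1 - 1))
    d2 = (n2 - 1) * winsorized_variance(b, trim) / (h2 * (h2 - 1))
    se = math.sqrt(d1 + d2)
    if se == 0:
        if tm1 == tm2:
            raise ValueError("statistic undefined: zero robust variance, equal trimmed means")
        t, df, p = math.inf * np.sign(tm1 - tm2), float(h1 + h2 - 2), 0.0
    else:
        t = (tm1 - tm2) / se
        df = (d1 + d2) ** 2 / (d1**2 / (h1 - 1) + d2**2 / (h2 - 1))
        p = 2 * sps.t.sf(abs(t), df)

    # explanatory measure of effect size
    fitted = np.r_[np.full(n1, tm1), np.full(n2, tm2)]
    var_fitted = float(np.var(fitted, ddof=1))
    pooled = np.r_[a, b]
    var_total = winsorized_variance(pooled, trim) / _winvar_normal(trim)
    xi = 0.0 if var_total == 0 else min(1.0, math.sqrt(var_fitted / var_total))
    return GroupComparisonResult(
        method="yuen_t",
        statistic=float(t),
        df=float(df),
        p=float(p),
        effect_size=xi,
        effect_label="xi",
        extra={"trim": trim, "trimmed_means": (tm1, tm2)},
    )


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

def ols_hc3(y, X, robust: bool = True, standardized: bool = True):
    """OLS with optional HC3 heteroskedasticity-consistent covariance.

    ``X`` is a DataFrame / 2-D array of predictors (no constant column; one
    is added). Returns a dict with the fitted statsmodels results plus
    standardized betas (z-scored response and predictors) and the model F.
    """
    import pandas as pd

    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if X.shape[1] > 1 else tuple(X.columns)
        raise ValueError(f"rank-deficient design; near-collinear columns: {worst}")
    fit = sm.OLS(y, Xc).fit(cov_type="HC3" if robust else "nonrobust")

    betas = {}
    if standardized:
        sy = y.std(ddof=1)
        for col in X.columns:
            sx = X[col].std(ddof=1)
            betas[col] = float(fit.params[col] * sx / sy) if sy > 0 and sx > 0 else np.nan
    return {
        "fit": fit,
        "params": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
        "r2": float(fit.rsquared),
        "f": float(fit.fvalue),
        "df_model": float(fit.df_model),
        "df_resid": float(fit.df_resid),
        "standardized_beta": betas,
        "robust": robust,
    }


def vif(X) -> dict[str, float]:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j)."""
    import pandas as pd

    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least two predictors")
    Xc = sm.add_constant(X, has_constant="add")
    out = {}
    arr = Xc.to_numpy(float)
    for j, col in enumerate(X.columns, start=1):
        try:
            v = variance_inflation_factor(arr, j)
        except Exception:
            v = np.inf
        out[col] = float(v)
    return out


def levene_median(a, b) -> float:
    """p-value of the Brown-Forsythe (median-centred Levene) variance test."""
    return float(sps.levene(_as_clean(a), _as_clean(b), center="median").pvalue)


def holm_correct(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# --------------------------------------------------------------------------
# effect-size harmonization and theory comparison
# --------------------------------------------------------------------------

def effect_to_abs_d(kind: str, value: float, n1: int | None = None,
                    n2: int | None = None, df: float | None = None,
                    df_num: float | None = None) -> dict:
    """Convert a t, F(1, df) or r effect to |Cohen's d|.

    t:       |d| = |t| * sqrt(1/n1 + 1/n2)
    F(1,df): |d| = 2 * sqrt(F / df)
    r:       |d| = 2|r| / sqrt(1 - r^2)
    """
    kind = kind.lower()
    if kind == "t":
        if n1 is None or n2 is None:
            raise ValueError("t conversion needs group sizes")
        d = abs(value) * math.sqrt(1 / n1 + 1 / n2)
    elif kind == "f":
        if df_num is not None and df_num != 1:
            raise ValueError("only F(1, df) effects can be converted to d")
        if df is None:
            raise ValueError("F conversion needs the denominator df")
        d = 2 * math.sqrt(max(value, 0.0) / df)
    elif kind == "r":
        if abs(value) >= 1:
            raise ValueError("r conversion needs |r| < 1")
        d = 2 * abs(value) / math.sqrt(1 - value**2)
    else:
        raise ValueError(f"unsupported effect kind {kind!r}")
    return {"abs_d": float(d), "conversion": f"{kind}_to_d"}


def compare_to_main_ci(abs_d: Mapping[str, float], ci: tuple[float, float]) -> dict:
    """Verdict per theory: |d| inside/outside the main-analysis |d| CI.

    The CI is taken on the absolute-d scale as a closed interval, so values
    equal to an endpoint count as inside.
    """
    lo, hi = sorted(abs(c) for c in ci)
    verdicts = {k: ("inside" if lo <= v <= hi else "outside") for k, v in abs_d.items()}
    return {
        "verdicts": verdicts,
        "any_outside": any(v == "outside" for v in verdicts.values()),
    }
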