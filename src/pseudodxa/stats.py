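"""Statistical procedures for the cohort analysis.

Covers descriptive comparisons (pooled-variance t-tests, D'Agostino-Pearson
normality), per-group linear age adjustment to a target age, OLS
regressions, the ANCOVA slope/elevation comparison with midpoint-shifted
elevations, percent-of-mean differences, multivariable models with a
VIF-screening loop, and the two-way random-effects ICC.

OLS fits go through statsmodels; the conventions specific to this analysis
(midpoint shifting of x before reading off per-group elevations, the
percent-of-mean difference, the VIF > 10 removal loop) are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor


class StatsError(ValueError):
    """Invalid input to a statistical procedure."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    resid_se: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


@dataclass
class AncovaResult:
    """Two-group regression comparison with midpoint elevations.

    Elevations are the per-group intercepts after shifting x by the midpoint
    of the pooled x range; ``elevation_diff`` is group1 minus group0 (male
    minus female when sex is coded 0/1) and ``pct_difference`` uses the
    percent-of-mean convention.
    """

    slope_p: float
    elevation_p: float
    common_slope: float
    group_offset: float  # group coefficient of the common-slope model
    groups: tuple
    elevations: tuple[float, float]
    elevation_cis: tuple[tuple[float, float], tuple[float, float]]
    elevation_diff: float
    elevation_diff_ci: tuple[float, float]
    pct_difference: float
    midpoint: float
    per_group: dict = field(default_factory=dict, repr=False)


@dataclass
class TermStats:
    name: str
    b: float
    ci: tuple[float, float]
    beta_std: float
    p_value: float
    vif: float


@dataclass
class MultivarModel:
    terms: list[TermStats]
    intercept: float
    adj_r2: float
    n: int
    removed: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermStats:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# simple tests
# ---------------------------------------------------------------------------

def independent_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError(f"each group needs n >= 2, got {len(a)} and {len(b)}")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K^2, p); needs n >= 20."""
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise StatsError(f"D'Agostino-Pearson test needs n >= 20, got {len(values)}")
    res = sps.normaltest(values)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# age adjustment
# ---------------------------------------------------------------------------

def age_adjust(
    table: pd.DataFrame,
    variables: list[str],
    target_age: float = 65.0,
    by_group: str | None = "sex",
    age_col: str = "age",
) -> tuple[pd.DataFrame, dict]:
    """Adjust variables to a common age by within-group linear regression.

    Within each group, ``value ~ age`` is fit by least squares and each
    observation is moved along that line: ``adjusted = observed + slope *
    (target_age - age)``.  Returns the adjusted table (copy) and a log of the
    adjustment slopes per (group, variable).
    """
    if age_col not in table:
        raise StatsError(f"age column {age_col!r} not present")
    out = table.copy()
    slopes: dict = {}
    groups = [(None, table.index)] if by_group is None else [
        (g, table.index[table[by_group] == g]) for g in sorted(table[by_group].unique())
    ]
    for g, idx in groups:
        if len(idx) < 3:
            raise StatsError(f"group {g!r} has n = {len(idx)} < 3; cannot age-adjust")
        age = table.loc[idx, age_col].to_numpy(dtype=float)
        for var in variables:
            y = table.loc[idx, var].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 3:
                raise StatsError(f"group {g!r}, variable {var!r}: fewer than 3 finite values")
            slope = (
                0.0
                if np.ptp(age[ok]) == 0
                else float(np.polyfit(age[ok], y[ok], 1)[0])
            )
            slopes[(g, var)] = slope
            out.loc[idx, var] = y + slope * (target_age - age)
    return out, slopes


# ---------------------------------------------------------------------------
# regression and ANCOVA
# ---------------------------------------------------------------------------

def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with CIs for both coefficients."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("x and y must have equal length")
    if len(x) < 3:
        raise StatsError(f"regression needs n >= 3, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise StatsError("zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(x),
        resid_se=float(np.sqrt(fit.mse_resid)),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
    )


def pct_difference(e_female: float, e_male: float) -> float:
    """Percent-of-mean difference, 100 * (M - F) / ((M + F) / 2)."""
    if e_female <= 0 or e_male <= 0:
        raise StatsError("percent-of-mean difference requires positive elevations")
    return 100.0 * (e_male - e_female) / ((e_male + e_female) / 2.0)


def ancova_compare(x, y, group) -> AncovaResult:
    """Compare two groups' regressions of y on x.

    (1) slope equality: F-test of the group-by-x interaction; (2) elevation
    equality: F-test of the group term in the common-slope model; (3)
    elevations: x is shifted by the midpoint of the pooled x range and each
    group refit, the intercepts (with 95% CIs) being the elevations.  The
    difference CI combines the per-group intercept SEs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise StatsError(f"exactly two groups required, got {len(levels)}")
    masks = [group == g for g in levels]
    for g, m in zip(levels, masks):
        if m.sum() < 3:
            raise StatsError(f"group {g!r} has n < 3")
        if np.ptp(x[m]) == 0:
            raise StatsError(f"group {g!r} has zero x-variance")

    g01 = (group == levels[1]).astype(float)
    X_full = np.column_stack([np.ones_like(x), x, g01, x * g01])
    fit_full = sm.OLS(y, X_full).fit()
    slope_p = float(fit_full.pvalues[3])

    X_common = X_full[:, :3]
    fit_common = sm.OLS(y, X_common).fit()
    elevation_p = float(fit_common.pvalues[2])
    common_slope = float(fit_common.params[1])

    midpoint = float((x.min() + x.max()) / 2.0)
    elevations, cis, ses, fits = [], [], [], {}
    for g, m in zip(levels, masks):
        fit = sm.OLS(y[m], sm.add_constant(x[m] - midpoint)).fit()
        elevations.append(float(fit.params[0]))
        ci = fit.conf_int(alpha=0.05)
        cis.append((float(ci[0][0]), float(ci[0][1])))
        ses.append(float(fit.bse[0]))
        fits[g] = fit
    diff = elevations[1] - elevations[0]
    se_diff = float(np.hypot(*ses))
    df = len(x) - 4
    tq = sps.t.ppf(0.975, df)
    mean_elev = (elevations[0] + elevations[1]) / 2.0
    return AncovaResult(
        slope_p=slope_p,
        elevation_p=elevation_p,
        common_slope=common_slope,
        group_offset=float(fit_common.params[2]),
        groups=tuple(levels.tolist()),
        elevations=(elevations[0], elevations[1]),
        elevation_cis=(cis[0], cis[1]),
        elevation_diff=float(diff),
        elevation_diff_ci=(float(diff - tq * se_diff), float(diff + tq * se_diff)),
        pct_difference=float(100.0 * diff / mean_elev) if mean_elev != 0 else np.nan,
        midpoint=midpoint,
        per_group=fits,
    )


# ---------------------------------------------------------------------------
# multivariable regression with VIF screening
# ---------------------------------------------------------------------------

def multivariable_fit(
    y, predictors: pd.DataFrame, vif_threshold: float = 10.0
) -> MultivarModel:
    """OLS of y on several predictors with a VIF-screening loop.

    Reports unstandardized B with 95% CI, standardized beta
    (B * SD(x) / SD(y)), per-term p, and VIF; while any VIF exceeds the
    threshold the maximum-VIF term is removed and the model refit, with the
    removals logged.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float).copy()
    if len(y) <= X.shape[1] + 1:
        raise StatsError(f"n = {len(y)} too small for {X.shape[1]} predictors")
    removed: list[str] = []
    while True:
        if X.shape[1] == 0:
            raise StatsError("VIF screening removed every predictor")
        exog = sm.add_constant(X)
        with np.errstate(divide="ignore"):
            vifs = {
                col: float(variance_inflation_factor(exog.to_numpy(), j + 1))
                for j, col in enumerate(X.columns)
            }
        if X.shape[1] == 1 or max(vifs.values()) <= vif_threshold:
            break
        worst = max(vifs, key=vifs.get)  # type: ignore[arg-type]
        removed.append(worst)
        X = X.drop(columns=[worst])

    exog = sm.add_constant(X)
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    sd_y = y.std(ddof=1)
    terms = []
    for col in X.columns:
        b = float(fit.params[col])
        terms.append(
            TermStats(
                name=col,
                b=b,
                ci=(float(ci.loc[col, 0]), float(ci.loc[col, 1])),
                beta_std=float(b * X[col].std(ddof=1) / sd_y),
                p_value=float(fit.pvalues[col]),
                vif=vifs[col],
            )
        )
    return MultivarModel(
        terms=terms,
        intercept=float(fit.params["const"]),
        adj_r2=float(fit.rsquared_adj),
        n=len(y),
        removed=removed,
    )


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def icc(ratings) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, k_raters) array with no missing cells;
    returns the ICC and its 95% CI.
    """
    import pingouin as pg

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise StatsError("ratings must be 2D (subjects x raters)")
    n, k = ratings.shape
    if n < 5 or k < 2:
        raise StatsError(f"need >= 5 subjects and >= 2 raters, got {ratings.shape}")
    if not np.isfinite(ratings).all():
        raise StatsError("missing or non-finite cells in ratings")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # absolute-agreement single-measure row; label varies across pingouin versions
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))
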