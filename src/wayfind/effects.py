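"""Association analyses: standardized effect sizes, factorial ANOVA,
random-slope mixed models, default Bayes factors, and slope-indicator
correlations.

Conventions: gender is coded male = 1, female = 0 (positive coefficients =
male advantage); education enters as tertiary = 1, secondary-and-lower = 0
(positive coefficients and positive Hedge's g = tertiary advantage).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import integrate, stats

from .errors import DegenerateInputError, FitError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectEstimate:
    """Bias-corrected standardized mean difference with a 95% CI."""

    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    bf10: float | None = None


@dataclass(frozen=True)
class SlopeEstimate:
    """Total education slope (tertiary advantage, WF units) of one group."""

    group_id: object
    slope: float
    se: float


def hedges_g(
    group_a, group_b, ci_method: str = "normal"
) -> EffectEstimate:
    """Hedge's g of group_a minus group_b with a 95% confidence interval.

    g = J * (mean_a - mean_b) / s_pooled with the small-sample correction
    J = 1 - 3 / (4*(n1+n2-2) - 1).  The default CI is the normal
    approximation g +/- 1.96 * SE with
    SE^2 = (n1+n2)/(n1*n2) + g^2 / (2*(n1+n2-2)); ``ci_method="noncentral"``
    inverts the noncentral-t distribution instead.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
    if s_pooled == 0:
        raise DegenerateInputError("pooled standard deviation is zero")
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * (a.mean() - b.mean()) / s_pooled
    if ci_method == "normal":
        se = math.sqrt((n1 + n2) / (n1 * n2) + g * g / (2.0 * df))
        lo, hi = g - 1.96 * se, g + 1.96 * se
    elif ci_method == "noncentral":
        d = g / J
        nc = d * math.sqrt(n1 * n2 / (n1 + n2))
        scale = J * math.sqrt((n1 + n2) / (n1 * n2))
        lo_nc, hi_nc = stats.nct.interval(0.95, df, nc)
        lo, hi = lo_nc * scale, hi_nc * scale
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return EffectEstimate(g=float(g), ci_low=float(lo), ci_high=float(hi),
                          n1=n1, n2=n2)


def g_by_age_window(
    cohort: pd.DataFrame,
    window_width: int = 5,
    outcome: str = "wf",
) -> pd.DataFrame:
    """Education Hedge's g within consecutive age windows.

    Windows are left-closed [a, a + width) anchored at the cohort minimum
    age and labelled by their midpoint.  Windows where either merged
    education class has fewer than 2 members are omitted (count logged).

    Returns ``(center, g, ci_low, ci_high, n1, n2)``.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    a0 = int(cohort["age"].min())
    rows, skipped = [], 0
    for start in range(a0, int(cohort["age"].max()) + 1, window_width):
        win = cohort[(cohort["age"] >= start) & (cohort["age"] < start + window_width)]
        ter = win.loc[win["education2"] == "tertiary", outcome]
        sec = win.loc[win["education2"] == "secondary_and_lower", outcome]
        if len(ter) < 2 or len(sec) < 2:
            if not win.empty:
                skipped += 1
            continue
        est = hedges_g(ter, sec)
        rows.append({"center": start + window_width / 2.0, "g": est.g,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "n1": est.n1, "n2": est.n2})
    if skipped:
        logger.info("g_by_age_window: omitted %d windows with a group < 2", skipped)
    return pd.DataFrame(rows, columns=["center", "g", "ci_low", "ci_high", "n1", "n2"])


def prepare_analysis_frame(
    cohort: pd.DataFrame, scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge WF scores into the cohort and add numeric model codes.

    Adds ``gender_male`` (male = 1) and ``tertiary`` (tertiary = 1).
    """
    df = cohort.merge(scores, on="participant_id", how="inner") \
        if scores is not None else cohort.copy()
    df["gender_male"] = (df["gender"] == "male").astype(float)
    df["tertiary"] = (df["education2"] == "tertiary").astype(float)
    return df


def anova_main_effects(
    cohort: pd.DataFrame,
    formula: str | None = None,
    ss_type: int = 2,
    outcome: str = "wf",
) -> pd.DataFrame:
    """Factorial ANOVA of the WF regression on age, gender and education.

    Fits ``wf ~ age * gender_male * tertiary`` by OLS and summarizes the
    terms with Type II F tests by default (order-invariant; ``ss_type=1``
    gives sequential sums of squares for comparison).  Returns the
    statsmodels ANOVA table (F, df, p per term).
    """
    df = cohort
    if outcome not in df.columns:
        raise ValueError(f"cohort lacks outcome column {outcome!r}")
    if float(np.var(df[outcome].to_numpy(float))) == 0.0:
        raise DegenerateInputError("outcome has zero variance")
    formula = formula or f"{outcome} ~ age * gender_male * tertiary"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise FitError("design matrix is rank deficient")
    return sm.stats.anova_lm(fit, typ=ss_type)


def fit_random_slope_model(
    cohort: pd.DataFrame,
    grouping: str,
    outcome: str = "wf",
) -> tuple[pd.Series, list[SlopeEstimate]]:
    """Linear mixed model with a random intercept and education slope.

    Fixed effects: age, gender, and an overall education effect; random
    effects: per-group intercept and education-slope deviation with an
    unstructured 2x2 covariance, estimated by maximum likelihood (ML, not
    REML).  The per-group total slope is the fixed education coefficient
    plus the group's predicted (BLUP) deviation; its SE combines the fixed
    coefficient's SE with the BLUP's conditional SD.

    ``grouping`` is the cohort column holding the cluster id (e.g.
    ``"country"`` or ``"level_id"``).  Requires >= 3 groups and both merged
    education classes within every group.
    """
    df = cohort
    groups = df[grouping].unique()
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for a random-slope model")
    class_counts = df.groupby(grouping)["tertiary"].agg(["min", "max"])
    incomplete = class_counts[(class_counts["min"] == class_counts["max"])]
    if len(incomplete):
        raise ValueError(
            f"groups missing an education class: {list(incomplete.index)}")

    model = smf.mixedlm(
        f"{outcome} ~ age + gender_male + tertiary",
        data=df, groups=df[grouping], re_formula="~tertiary")
    result = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidate = model.fit(reml=False, method=method)
        result = result or candidate
        if candidate.converged:
            result = candidate
            break
    singular = np.linalg.det(np.asarray(result.cov_re)) <= 1e-12
    if not result.converged and not singular:
        raise FitError("mixed model did not converge", result.summary())
    if singular:
        # ML puts a variance component on the boundary; estimates remain usable.
        logger.warning("random-effect covariance is singular; fit retained")

    fe = result.fe_params
    fe_se = result.bse_fe["tertiary"]
    slopes = []
    for gid in sorted(pd.unique(df[grouping])):
        re = result.random_effects[gid]
        cond = result.random_effects_cov[gid]
        blup_var = float(np.asarray(cond)[1, 1]) if np.asarray(cond).shape == (2, 2) \
            else float(cond.loc["tertiary", "tertiary"])
        slopes.append(SlopeEstimate(
            group_id=gid,
            slope=float(fe["tertiary"] + re["tertiary"]),
            se=float(np.sqrt(fe_se ** 2 + max(blup_var, 0.0))),
        ))
    return fe, slopes


def slopes_frame(slopes: list[SlopeEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"group_id": s.group_id, "slope": s.slope, "se": s.se} for s in slopes
    ])


def fixed_interaction_model(
    cohort: pd.DataFrame, ss_type: int = 2, outcome: str = "wf"
) -> pd.DataFrame:
    """OLS with country as categorical and an education x country term.

    ``wf ~ age + gender_male + tertiary * C(country)``, summarized with
    Type II F tests — the fixed-effect analogue of the random-slope model.
    """
    if cohort["country"].nunique() < 2:
        raise ValueError("need at least 2 countries")
    fit = smf.ols(f"{outcome} ~ age + gender_male + tertiary * C(country)",
                  data=cohort).fit()
    return sm.stats.anova_lm(fit, typ=ss_type)


def bayes_factor_two_sample(group_a, group_b, r: float = math.sqrt(2) / 2) -> float:
    """Default JZS two-sample Bayes factor BF10 (two-sided).

    Cauchy prior with scale ``r`` on the standardized group difference;
    the marginal likelihood is evaluated by adaptive quadrature over the
    inverse-chi-square mixing variable.  BF10 > 1 favors a difference.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    t, _ = stats.ttest_ind(a, b, equal_var=True)
    t = float(t)
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)

    def integrand(g: float) -> float:
        w = 1.0 + n_eff * g * r * r
        return (
            w ** -0.5
            * (1.0 + t * t / (w * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * math.pi) ** -0.5 * g ** -1.5 * math.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * num + 1e-12:
        raise FitError("JZS quadrature failed", num, err)
    denom = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / denom


def correlate_slopes_with_indicator(
    slopes: list[SlopeEstimate] | pd.DataFrame,
    indicator: pd.Series | dict,
) -> tuple[float, float, int]:
    """Pearson correlation of per-group slopes with a per-group indicator.

    Only groups present in both inputs enter; returns (r, p, n) with a
    two-sided p from the t transform on n - 2 df.  Requires >= 3 matched
    groups; a constant input is degenerate.
    """
    df = slopes if isinstance(slopes, pd.DataFrame) else slopes_frame(slopes)
    ind = pd.Series(indicator)
    merged = df.set_index("group_id")["slope"].to_frame("slope").join(
        ind.rename("indicator"), how="inner").dropna()
    n = len(merged)
    if n < 3:
        raise ValueError("need at least 3 matched groups")
    if merged["slope"].nunique() == 1 or merged["indicator"].nunique() == 1:
        raise DegenerateInputError("constant slopes or indicator: correlation undefined")
    r, p = stats.pearsonr(merged["slope"], merged["indicator"])
    return float(r), float(p), n
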