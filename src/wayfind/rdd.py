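"""Sharp regression-discontinuity analysis of a school-leaving-age reform.

The outcome (WF, or training performance for the placebo) is regressed on
birth year and a 0/1 dummy that switches on at a candidate cutoff year c:
``outcome ~ 1 + birthyear + 1[birthyear >= c]``.  Birth year is centered at
the cutoff inside the fit, which leaves the dummy coefficient — the jump at
the cutoff — identical to the uncentered parameterization.  Sweeping c over
integer years around the first reform-affected cohort and checking that the
largest jump lands on that cohort is the causal localization test; the
pre/post gap extrapolated from two free regression lines, rescaled by
SD(WF) x 15, expresses the effect in IQ-point units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RDDFit:
    """One discontinuity regression at cutoff year ``cutoff``."""

    cutoff: int
    coefficient: float
    se: float
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class GapEstimate:
    """Extrapolated pre/post gap at the cutoff, with IQ-unit rescaling."""

    cutoff: int
    pre_value: float
    pre_ci: tuple[float, float]
    post_value: float
    post_ci: tuple[float, float]
    delta_wf: float
    sd_wf: float
    iq_points: float
    n_pre: int
    n_post: int


def fit_rdd(
    cohort: pd.DataFrame,
    cutoff: int,
    window: float | None = None,
    outcome: str = "wf",
) -> RDDFit:
    """OLS of outcome on intercept, centered birth year, and the cutoff dummy.

    ``window``, if given, restricts to birth years within window/2 of the
    cutoff.  Participants born exactly in the cutoff year count as post
    (dummy = 1).  Raises ``ValueError`` when either side is empty.
    """
    df = cohort
    if window is not None:
        half = window / 2.0
        df = df[(df["birth_year"] >= cutoff - half) & (df["birth_year"] <= cutoff + half)]
    year = df["birth_year"].to_numpy(float)
    y = df[outcome].to_numpy(float)
    post = year >= cutoff
    if len(df) == 0 or not post.any() or post.all():
        raise ValueError(f"one-sided data at cutoff {cutoff}")
    X = np.column_stack([np.ones_like(year), year - cutoff, post.astype(float)])
    fit = sm.OLS(y, X).fit()
    coef = float(fit.params[2])
    se = float(fit.bse[2])
    if se == 0.0 or not np.isfinite(se):
        # Noiseless data: the jump is exact.
        t = np.inf * np.sign(coef) if coef != 0 else 0.0
        p = 0.0 if coef != 0 else 1.0
        se = 0.0
    else:
        t = float(fit.tvalues[2])
        p = float(fit.pvalues[2])
    return RDDFit(cutoff=int(cutoff), coefficient=coef, se=se, t=float(t),
                  p=float(p), n=len(df))


def sweep_cutoffs(
    cohort: pd.DataFrame,
    center_year: int = 1957,
    halfwidth: int = 5,
    outcome: str = "wf",
) -> tuple[list[RDDFit], int]:
    """Fit every integer cutoff in [center - halfwidth, center + halfwidth].

    The caller passes the analysis-window cohort (participants born within
    the design window around the reform's first affected cohort); every
    candidate cutoff is fit on that same fixed sample.  Candidates with
    one-sided data (the lower edge of the grid) are skipped with a logged
    warning.  Returns the fits and the cutoff with the largest dummy
    coefficient; exact ties break toward the center year with a warning.
    """
    df = cohort
    fits: list[RDDFit] = []
    for c in range(center_year - halfwidth, center_year + halfwidth + 1):
        try:
            fits.append(fit_rdd(df, c, window=None, outcome=outcome))
        except ValueError:
            logger.warning("sweep_cutoffs: cutoff %d has one-sided data; skipped", c)
    if len(fits) < 1:
        raise ValueError("no two-sided candidate cutoffs")
    best = max(fits, key=lambda f: f.coefficient)
    ties = [f for f in fits if f.coefficient == best.coefficient]
    if len(ties) > 1:
        logger.warning("sweep_cutoffs: tie among cutoffs %s; breaking toward %d",
                       [f.cutoff for f in ties], center_year)
        best = min(ties, key=lambda f: abs(f.cutoff - center_year))
    return fits, best.cutoff


def sweep_frame(fits: list[RDDFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {"cutoff": f.cutoff, "coef": f.coefficient, "se": f.se,
         "t": f.t, "p": f.p, "n": f.n} for f in fits
    ])


def pre_post_gap(
    cohort: pd.DataFrame,
    cutoff: int,
    outcome: str = "wf",
    sd_scope: str = "window",
) -> GapEstimate:
    """Two free regression lines on birth year, evaluated at the cutoff.

    pre_value extrapolates the pre-cutoff line to the cutoff year;
    post_value evaluates the post line there; delta_wf is their difference,
    and iq_points = delta_wf / SD(outcome) * 15 on the standard IQ scale
    (M = 100, SD = 15).  By default SD(outcome) is computed on the cohort
    passed in (the analysis window); ``sd_scope`` is recorded only.
    95% CIs come from each line's prediction SE at the cutoff.
    """
    year = cohort["birth_year"].to_numpy(float)
    pre = cohort[year < cutoff]
    post = cohort[year >= cutoff]
    if len(pre) < 3 or len(post) < 3:
        raise ValueError("each side of the cutoff needs at least 3 participants")

    def line_at_cutoff(df: pd.DataFrame) -> tuple[float, tuple[float, float]]:
        X = sm.add_constant(df["birth_year"].to_numpy(float) - cutoff)
        fit = sm.OLS(df[outcome].to_numpy(float), X).fit()
        pred = fit.get_prediction(np.array([[1.0, 0.0]]))
        value = float(pred.predicted_mean[0])
        if np.isfinite(pred.se_mean[0]) and fit.scale > 0:
            lo, hi = (float(v) for v in pred.conf_int()[0])
        else:
            lo = hi = value
        return value, (lo, hi)

    pre_value, pre_ci = line_at_cutoff(pre)
    post_value, post_ci = line_at_cutoff(post)
    delta = post_value - pre_value
    sd = float(cohort[outcome].std(ddof=1))
    return GapEstimate(
        cutoff=int(cutoff), pre_value=pre_value, pre_ci=pre_ci,
        post_value=post_value, post_ci=post_ci, delta_wf=delta, sd_wf=sd,
        iq_points=rescale_to_iq_points(delta, sd),
        n_pre=len(pre), n_post=len(post),
    )


def rescale_to_iq_points(delta_wf: float, sd_wf: float) -> float:
    """Express a WF gap in IQ points: delta / SD(WF) * 15."""
    if sd_wf <= 0:
        raise ValueError("SD(WF) must be positive")
    return delta_wf / sd_wf * 15.0


def placebo_rdd(
    cohort: pd.DataFrame,
    center_year: int = 1957,
    halfwidth: int = 5,
    outcome: str = "tp",
) -> tuple[list[RDDFit], dict]:
    """The same cutoff sweep on training performance (negative control).

    Education should not move pure motor skill, so no cutoff should show a
    significant jump.  Returns the fits plus a summary with the largest
    coefficient and its p-value.
    """
    if outcome not in cohort.columns or cohort[outcome].dropna().empty:
        raise ValueError(f"cohort lacks placebo outcome {outcome!r}")
    fits, best = sweep_cutoffs(cohort, center_year, halfwidth, outcome=outcome)
    top = max(fits, key=lambda f: f.coefficient)
    summary = {"max_coef": top.coefficient, "p": top.p, "cutoff": top.cutoff,
               "max_abs_t": max(abs(f.t) for f in fits)}
    return fits, summary
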