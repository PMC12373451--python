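# Methods

This note documents the generative model behind the synthetic cohorts, the
scoring and inference procedures, the numerical choices, and what the
package's tests do and do not establish about real data.

## Synthetic cohort model

Each participant i has demographics (age uniform over a configurable
range, default 19–70; gender with P(female) = 0.47; country drawn from
weighted codes; education in four classes with P(tertiary) = 0.70 split
60/40 into university/college and 90/10 into high-school/no-formal) and a
latent wayfinding skill

```
L_i = β_age (age_i − 40) + β_gender male_i
    + (β_edu + β_axe (age_i − 40) + u_c(i)) tertiary_i
    + a_c(i) + ε_i,          ε_i ~ N(0, σ²)
```

with per-country intercepts `a_c ~ N(0, σ_a²)` and education-slope
deviations `u_c = offset_c + N(0, σ_u²)`. Birth year is 2016 − age (the
data-collection-year convention; fractional birth dates ignored). An
optional school-leaving-age reform adds `complier_skill_gain` to a
`complier_fraction` of secondary-and-lower participants born in or after
the first affected year — the education *label* is unchanged, because the
reform moved the leaving age within the secondary tier, and the RDD must
detect an effect within observed education classes.

Trajectory lengths follow

```
tutorial:    TL_il = minTL_l · m_i
wayfinding:  TL_il = minTL_l · m_i · (1 + d_l · softplus(s − L_il + ε_il))
```

where `m_i = exp(|N(0, σ_m)|) ≥ 1` is a motor-skill factor (the folded
form keeps every length above the level's minimal path length, which a
plain log-normal would violate), `d_l` is the level's difficulty
parameter (non-decreasing in level id), `ε_il ~ N(0, σ_ε)` is
level-specific noise, and `s` is a location shift (default 6) that keeps
the softplus link in its near-linear regime. The link is strictly
positive and decreasing in skill, so higher skill gives stochastically
shorter trajectories. On harder levels the education component of skill
is amplified by `β_dxe (d_l − d_ref)` (d_ref = mean difficulty of the four
composite levels), which is what makes the per-level education slopes
grow with difficulty — a purely multiplicative `d_l` cannot, because
column standardization removes it.

### Calibration

Writing σ_L² for the variance of L, the standardized per-level
performance is approximately `(−L + ε_l)/√(σ_L² + σ_ε²)` in the linear
regime, so the four-level PC1 maps latent skill to WF with slope
`b ≈ 2/√(σ_L² + σ_ε²)`. The default σ_ε = 1.6 therefore makes one unit of
latent skill ≈ one unit of WF (b ≈ 1 at the default σ_L² ≈ 1.36), which
is what lets injected country-slope offsets be recovered on their own
scale. Defaults (β_age = −0.037, β_gender = 0.60, β_edu = 0.18,
β_axe = 0.0025 per year, β_dxe = 0.02 per difficulty unit, σ = 1,
σ_a = 0.10, σ_u = 0.05, σ_m = 0.2) were calibrated once so a default
cohort shows r(age, WF) ≈ −0.36, gender g ≈ 0.44, education g ≈ 0.12–0.15
growing with age, SD(WF) ≈ 1.4, and near-zero correlation between WF and
training performance; country offsets emulate a spread from a near-zero
education effect (IN) to slightly above average (RO).

What the generator does *not* emulate: non-uniform age pyramids,
education–age–country dependence, selection into the game, missing data,
level non-completion (every participant plays every catalogued level), or
2-D trajectory geometry. Passing tests therefore show the *pipeline*
recovers what was injected under clean sampling, not that real data meet
these assumptions.

## Inclusion filter

Single pass, in order: (1) completeness — all demographics present and at
least 11 distinct levels including 4 wayfinding levels; (2) age ≤ 70
(boundary kept: "above 70" removed); (3) country size ≥ 500 and merged
education-class imbalance ≤ 10 (max/min over the two merged classes,
infinite when a class is empty; ratio strictly above 10 excludes),
evaluated once on the already-filtered set without fixed-point iteration.
The four education classes merge to tertiary (university + college) vs
secondary-and-lower (high-school + no formal). The filter is idempotent
and row-order independent, and reports counts at every stage.

## Scoring

WF is the first principal component of the **correlation-matrix** PCA of
tutorial-normalized lengths (columns standardized with ddof = 1); the
paper-style covariance-of-ratios alternative is deliberately not offered,
since standardization is what guarantees "levels on the same scale"
regardless of level size. Sign is fixed by corr(WF, row mean) < 0, with
the positive-first-loading orientation as the tie-break at exactly zero
correlation. Lengths are not log-transformed. Participants missing a
tutorial or composite level are dropped and counted. Training performance
is Σ tutorial length / (cohort minimum at that level) ≥ 2; difficulty is
(median − min)/min of a level's lengths, scale-invariant and ≥ 0.

For level-clustered models, per-level scores are the negated
tutorial-normalized lengths divided by the level SD — scaled, not
centered, so the mixed model's random intercepts retain the level means
(centering makes the random-intercept variance exactly zero, a degenerate
boundary fit).

## Inference

* Hedge's g with the standard small-sample correction; SE² =
  (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂−2)); normal-approximation CI by default, a
  noncentral-t CI behind a flag. Age windows are left-closed [a, a+5)
  anchored at the cohort minimum age, labelled by midpoint; windows with a
  group smaller than 2 are omitted and logged.
* ANOVA: Type II sums of squares on the full factorial OLS (order
  invariant; Type I available for comparison). Gender is coded male = 1,
  education tertiary = 1, so positive coefficients mean male/tertiary
  advantage.
* Mixed models: ML (not REML), unstructured 2×2 random covariance,
  per-group slope = fixed effect + BLUP, SE = √(SE_fixed² + conditional
  BLUP variance). Optimizers are tried in sequence (lbfgs, bfgs, cg,
  powell); a boundary fit with singular random covariance is retained
  with a warning, any other non-convergence raises.
* Bayes factors: two-sample JZS with Cauchy scale √2/2 via adaptive
  quadrature over the inverse-chi-square mixing variable. Published
  Bayes-factor values from real data are not reproduction targets, since
  the original method was unspecified.
* RDD: birth year is centered at the cutoff (this changes the intercept
  only, not the dummy coefficient); the cutoff year itself belongs to the
  post side. The sweep grid is integer years; the caller supplies the
  analysis-window cohort and candidates with one-sided data are skipped
  with a warning (with a ±5-year window the lowest candidate always is).
  Ties in the argmax break toward the center year. The pre/post gap uses
  two free regression lines (no common slope), as a descriptive
  complement to the single-slope formal test; SD(WF) for IQ rescaling is
  computed on the window cohort (whole-cohort SD behind a flag).
  Noiseless piecewise-linear inputs are recovered at machine precision
  (se = 0 is reported with p = 0 for a nonzero step).

## Problem sizes and statistical design of the tests

Simulation-based checks use the sizes they state: slope recovery at
n = 100,000 over 10 seeds (assertions on seed means, since a single seed
carries an irreducible per-country sampling SE ≈ 0.02); type-I error over
400 cohorts of n = 2,000; localization and placebo sweeps over 50 cohorts
of n = 40,000; the difficulty analysis at 3,000 participants × 24 levels.
The acceptance script uses a 60,000-player cohort for the demographic
effects. One master seed feeds every stage through named substreams, so
identical configurations give byte-identical run reports.

Two power facts about the RDD design are worth stating explicitly. With
n = 40,000 spread uniformly over the 11 cohorts of a ±5-year window, the
residual variance of the cutoff dummy after the linear birth-year trend
is 0.0623, so a 0.05·SD step yields t ≈ 2.49 at the true cutoff — and
this is invariant to every noise parameter, because the step and the
residual scale together. The exact probability that the coefficient
argmax lands on the true cohort is then ≈ 0.82, so single-cohort
localization is suggestive rather than guaranteed at this effect size;
localization sharpens with n. Likewise the ±2·SE coverage of the dummy
estimate is nominally 95.45%, so coverage tests use binomial-consistent
bounds rather than the nominal rate itself.

## Known limitations

* The trajectory-length link is a modeling choice; no claim is made that
  real trajectory lengths follow a softplus-inflated form. Any strictly
  positive, decreasing-in-skill link preserves the package's invariants.
* With ten synthetic countries the slope–GDP correlation is dominated by
  the single low-GDP, low-effect country and is reported with wide
  uncertainty; the real-data analogue used 38 countries.
* BLUP-based per-group slopes are shrunken toward the fixed effect;
  the fixed interaction model (`education × country` OLS) is provided as
  the unshrunken alternative.
* No instrumental-variable estimation, fuzzy-RDD bandwidth selection, or
  modeling of post-70 selection bias beyond the exclusion filter.
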