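# wayfind

Does education improve spatial navigation ability — and is the link causal?
`wayfind` is a Python library for analysing that question the way large
mobile-game navigation studies do: it scores wayfinding performance from
game trajectory lengths, estimates how the education effect varies with
age, country and task difficulty, and tests causality with a
regression-discontinuity design around a school-leaving-age reform. A
built-in synthetic-cohort generator reproduces the statistical structure
such studies report, so the entire pipeline is runnable and testable
without access to any proprietary player data.

It is written for quantitative researchers in cognitive epidemiology and
behavioural science who want a reproducible, unit-tested reference
implementation of this analysis chain.

## The quantities it computes

**Wayfinding performance (WF).** Each player's trajectory length per level
(pixels) is divided by the sum of their two tutorial-level lengths, which
removes multiplicative motor/video-gaming skill. WF is the first principal
component of the standardized normalized lengths of wayfinding levels
6, 7, 8 and 11, sign-oriented so that corr(WF, mean normalized length) < 0
(higher WF = shorter, better trajectories).

**Effect sizes.** Group contrasts use bias-corrected Hedge's g,

&nbsp;&nbsp;&nbsp;&nbsp;g = J · (x̄₁ − x̄₂) / s_pooled,&nbsp;&nbsp;
J = 1 − 3 / (4(n₁+n₂−2) − 1),

with a normal-approximation 95% CI, overall and within 5-year age windows,
plus default JZS Bayes factors (Cauchy scale √2⁄2). The factorial
regression `WF ~ age * gender * education` is summarized with Type II
ANOVA F tests.

**Cross-country and cross-level heterogeneity.** Linear mixed models
(maximum likelihood) in the shorthand `WF ~ age + gender + 1 + education/group`
with a random intercept and random education slope per country (or per
level); per-group slopes are the fixed effect plus the BLUP deviation.
Level difficulty is `(median TL − min TL) / min TL`, and the per-level
education slopes are correlated with it.

**Causal analysis.** Sharp RDD: `WF ~ 1 + birthyear + 1[birthyear ≥ c]`,
sweeping the cutoff c over integer years around the first birth cohort
affected by the 1972 UK reform (born 1957). The extrapolated pre/post gap
ΔWF is rescaled to IQ points as ΔWF / SD(WF) × 15, and the same sweep on
training performance (a pure motor-skill score) serves as a placebo.

## Worked example

`examples/04_school_reform_rdd.py` simulates a UK-like cohort of 40,000
players born 1952–1962 in which 40% of would-be early school leavers born
from 1957 onward gain 1.2 WF units of latent skill, then runs the sweep:

```
discontinuity coefficient by candidate cutoff year:
 cutoff    coef     se       t      p     n
   1953  0.0104 0.0278  0.3759 0.7070 40000
   ...
   1957  0.1030 0.0279  3.6984 0.0002 40000
   1958 -0.0067 0.0278 -0.2415 0.8091 40000
   ...

largest discontinuity at c = 1957 (the first reform-affected birth cohort)

pre-line value at 1957:  -0.050 [-0.097, -0.003]
post-line value at 1957: 0.050 [0.017, 0.083]
delta WF = 0.100  ->  1.07 IQ points (delta / SD(WF) x 15)

placebo (training performance): max |t| = 1.82 (no significant discontinuity expected)
```

Only the true reform cohort shows a significant jump (t = 3.70); the
pre/post regression lines disagree at the cutoff by 0.100 WF units, worth
about 1.1 IQ points; and the motor-skill placebo stays flat — the pattern
expected if the extra school year, not confounding, moves wayfinding
ability. `examples/03_education_effects.py` prints the association side,
e.g. on a 40,000-player default cohort:

```
education Hedge's g = 0.174, 95% CI [0.153, 0.196] (n = 27946 tertiary vs 12054 lower)
```

The other examples cover cohort generation/filtering and scoring. A thin
CLI wraps the same pipeline (`wayfind all --seed 42 --out run/`, see
`wayfind --help`).

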