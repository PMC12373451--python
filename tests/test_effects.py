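"""Effect sizes, ANOVA, mixed models, Bayes factors, slope correlations."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wayfind as w
from wayfind.effects import slopes_frame


def hedges_oracle(a, b):
    """Independent exact-arithmetic evaluation of the g formula."""
    a = [Fraction(x).limit_denominator(10**12) for x in a]
    b = [Fraction(x).limit_denominator(10**12) for x in b]
    n1, n2 = len(a), len(b)
    ma, mb = sum(a) / n1, sum(b) / n2
    va = sum((x - ma) ** 2 for x in a) / (n1 - 1)
    vb = sum((x - mb) ** 2 for x in b) / (n2 - 1)
    df = n1 + n2 - 2
    var_pooled = ((n1 - 1) * va + (n2 - 1) * vb) / df
    J = 1 - Fraction(3, 4 * df - 1)
    g = float(J) * float(ma - mb) / math.sqrt(float(var_pooled))
    se = math.sqrt((n1 + n2) / (n1 * n2) + g * g / (2 * df))
    return g, g - 1.96 * se, g + 1.96 * se


class TestHedgesG:
    def test_matches_exact_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        cases = [([2.0, 4.0], [1.0, 3.0])]
        for _ in range(5):
            cases.append((rng.normal(0, 1, 15).tolist(),
                          rng.normal(0.4, 1.2, 11).tolist()))
        for a, b in cases:
            est = w.hedges_g(a, b)
            g, lo, hi = hedges_oracle(a, b)
            assert est.g == pytest.approx(g, abs=1e-10)
            assert est.ci_low == pytest.approx(lo, abs=1e-10)
            assert est.ci_high == pytest.approx(hi, abs=1e-10)

    def test_identical_groups_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        est = w.hedges_g(x, x)
        assert est.g == pytest.approx(0.0)
        assert est.ci_low < 0 < est.ci_high

    def test_antisymmetry(self):
        a, b = [2.0, 4.0, 5.0], [1.0, 3.0]
        assert w.hedges_g(a, b).g == pytest.approx(-w.hedges_g(b, a).g)

    def test_zero_pooled_variance_degenerate(self):
        with pytest.raises(w.DegenerateInputError):
            w.hedges_g([1.0, 1.0], [2.0, 2.0])

    def test_noncentral_ci_brackets_g(self):
        est = w.hedges_g([2.0, 4.0, 6.0, 5.0], [1.0, 3.0, 2.0],
                         ci_method="noncentral")
        assert est.ci_low <= est.g <= est.ci_high


def _single_country(**kw):
    base = dict(countries=(("AA", 1.0, 0.0),), country_slope_sd=0.0,
                country_intercept_sd=0.0, beta_difficulty_x_education=0.0)
    base.update(kw)
    return w.GeneratorConfig(**base)


def _frame(cfg, n_wayfinding=4):
    participants, traj, levels = w.simulate_dataset(cfg, n_wayfinding)
    participants = participants.copy()
    participants["education2"] = w.merge_education(participants["education4"])
    wf = w.compute_wf(w.normalize_lengths(traj, levels))
    return w.prepare_analysis_frame(participants, wf)


class TestGByAgeWindow:
    def test_education_effect_grows_with_age(self):
        """Positive age-by-education interaction shows as a rising g trend."""
        for seed in range(10):
            frame = _frame(_single_country(
                n_participants=20_000, beta_age_x_education=0.005, seed=seed))
            gw = w.g_by_age_window(frame)
            slope = stats.linregress(gw["center"], gw["g"]).slope
            assert slope > 0, f"seed {seed}: non-positive trend {slope}"

    def test_null_education_effect_small_everywhere(self):
        frame = _frame(_single_country(
            n_participants=100_000, beta_education=0.0,
            beta_age_x_education=0.0, prop_tertiary_base=0.5,
            age_range=(19, 68), seed=12345))
        gw = w.g_by_age_window(frame)
        assert len(gw) == 10
        assert (gw["g"].abs() < 0.05).all()

    def test_single_window_cohort(self):
        frame = _frame(_single_country(n_participants=2000, age_range=(30, 33),
                                       seed=2))
        gw = w.g_by_age_window(frame)
        assert len(gw) == 1


class TestAnova:
    def test_f_equals_squared_t_for_two_group_design(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "wf": np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)]),
            "tertiary": np.repeat([0.0, 1.0], 40),
        })
        table = w.anova_main_effects(frame, formula="wf ~ tertiary")
        t = stats.ttest_ind(frame.loc[frame["tertiary"] == 1, "wf"],
                            frame.loc[frame["tertiary"] == 0, "wf"]).statistic
        assert table.loc["tertiary", "F"] == pytest.approx(t ** 2, rel=1e-10)

    def test_zero_variance_outcome_degenerate(self):
        frame = pd.DataFrame({"wf": np.zeros(10), "age": np.arange(10.0),
                              "gender_male": [0.0, 1.0] * 5,
                              "tertiary": [0.0] * 5 + [1.0] * 5})
        with pytest.raises(w.DegenerateInputError):
            w.anova_main_effects(frame)

    def test_age_education_interaction_detected(self):
        """An injected age x education interaction reaches p < 0.01."""
        for seed in range(3):
            frame = _frame(_single_country(n_participants=200_000, seed=seed))
            table = w.anova_main_effects(frame)
            assert table.loc["age:tertiary", "PR(>F)"] < 0.01

    def test_type_i_and_type_ii_available(self, default_frame):
        t2 = w.anova_main_effects(default_frame, ss_type=2)
        t1 = w.anova_main_effects(default_frame, ss_type=1)
        assert set(t2.index) == set(t1.index)


class TestRandomSlopes:
    def test_identical_groups_get_identical_slopes(self):
        frame = _frame(_single_country(n_participants=3000, seed=8))
        stacked = pd.concat(
            [frame.assign(country=c) for c in ("AA", "BB", "CC")],
            ignore_index=True)
        _, slopes = w.fit_random_slope_model(stacked, "country")
        values = [s.slope for s in slopes]
        assert np.allclose(values, values[0], atol=1e-6)

    def test_sign_coherence_with_injected_positive_effect(self):
        """Positive education effect -> positive mean country slope and g."""
        for seed in range(3):
            cfg = w.GeneratorConfig(n_participants=20_000, seed=seed)
            frame = _frame(cfg)
            ter = frame.loc[frame["education2"] == "tertiary", "wf"]
            sec = frame.loc[frame["education2"] == "secondary_and_lower", "wf"]
            assert w.hedges_g(ter, sec).g > 0
            _, slopes = w.fit_random_slope_model(frame, "country")
            assert np.mean([s.slope for s in slopes]) > 0

    def test_requires_both_classes_per_group(self):
        frame = _frame(_single_country(n_participants=600, seed=3))
        frame = frame.assign(country=np.where(frame.index % 3 == 0, "AA",
                             np.where(frame.index % 3 == 1, "BB", "CC")))
        frame.loc[frame["country"] == "AA", "tertiary"] = 1.0
        with pytest.raises(ValueError):
            w.fit_random_slope_model(frame, "country")


class TestFixedInteraction:
    def test_identical_countries_no_interaction(self):
        frame = _frame(_single_country(n_participants=2000, seed=4))
        stacked = pd.concat(
            [frame.assign(country=c) for c in ("AA", "BB")], ignore_index=True)
        table = w.fixed_interaction_model(stacked)
        inter = [ix for ix in table.index if ":" in ix][0]
        assert table.loc[inter, "F"] < 1e-6

    def test_opposite_country_effects_detected(self):
        cfg = w.GeneratorConfig(
            n_participants=20_000, seed=6,
            countries=(("AA", 0.5, 0.3), ("BB", 0.5, -0.3)),
            country_slope_sd=0.0, country_intercept_sd=0.0,
            beta_difficulty_x_education=0.0)
        table = w.fixed_interaction_model(_frame(cfg))
        inter = [ix for ix in table.index if ":" in ix][0]
        assert table.loc[inter, "PR(>F)"] < 0.001

    def test_single_country_rejected(self):
        frame = _frame(_single_country(n_participants=500, seed=1))
        with pytest.raises(ValueError):
            w.fixed_interaction_model(frame)


class TestBayesFactor:
    def test_large_identical_samples_favor_null(self):
        x = np.linspace(-3, 3, 500)
        assert w.bayes_factor_two_sample(x, x) < 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 40), rng.normal(0.8, 1, 35)
        assert w.bayes_factor_two_sample(a, b) == pytest.approx(
            w.bayes_factor_two_sample(b, a), rel=1e-9)

    def test_matches_independent_jzs_evaluation(self):
        """Cross-check the quadrature against pingouin's JZS implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        t = stats.ttest_ind(a, b).statistic
        ours = w.bayes_factor_two_sample(a, b)
        theirs = float(pingouin.bayesfactor_ttest(
            t, nx=50, ny=50, paired=False, r=math.sqrt(2) / 2))
        assert ours == pytest.approx(theirs, rel=0.01)


class TestSlopeIndicatorCorrelation:
    def _slopes(self, values):
        return [w.SlopeEstimate(group_id=i, slope=v, se=0.1)
                for i, v in enumerate(values)]

    def test_identity_indicator_perfect_correlation(self):
        slopes = self._slopes([0.1, 0.2, 0.3, 0.4])
        r, p, n = w.correlate_slopes_with_indicator(
            slopes, {i: s.slope for i, s in enumerate(slopes)})
        assert r == pytest.approx(1.0)
        assert p < 1e-6
        assert n == 4

    def test_constant_indicator_degenerate(self):
        with pytest.raises(w.DegenerateInputError):
            w.correlate_slopes_with_indicator(
                self._slopes([0.1, 0.2, 0.3]), {0: 1.0, 1: 1.0, 2: 1.0})

    def test_too_few_matches_rejected(self):
        with pytest.raises(ValueError):
            w.correlate_slopes_with_indicator(
                self._slopes([0.1, 0.2, 0.3]), {0: 1.0, 1: 2.0})


def test_injected_g_recovered_through_full_pipeline():
    """With a near-linear link, the standardized education effect survives
    the trajectory simulation and PCA composite (mean over 10 seeds)."""
    recovered = []
    for seed in range(10):
        cfg = _single_country(n_participants=50_000, beta_age=0.0,
                              beta_gender=0.0, beta_education=0.3,
                              beta_age_x_education=0.0, noise_sd=1.0,
                              level_noise_sd=0.3, seed=seed)
        frame = _frame(cfg)
        ter = frame.loc[frame["education2"] == "tertiary", "wf"]
        sec = frame.loc[frame["education2"] == "secondary_and_lower", "wf"]
        recovered.append(w.hedges_g(ter, sec).g)
    assert np.mean(recovered) == pytest.approx(0.3, abs=0.03)
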