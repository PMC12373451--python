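"""Synthetic cohort and trajectory-length generator.

Produces participant tables and per-level trajectory lengths with the
statistical structure the downstream analysis assumes:

* wayfinding skill declines linearly with age;
* males hold an average advantage;
* tertiary education confers an advantage that grows with age and with
  level difficulty;
* the education effect varies across countries (random intercepts and
  random education slopes);
* an optional school-leaving-age reform raises the latent skill of a
  fraction of would-be early school leavers ("compliers") born from the
  first affected cohort onward, without changing their education label —
  the reform moved the leaving age within the secondary tier, so its
  effect must be detectable *within* observed education classes.

Latent skill is mapped to trajectory lengths through a strictly positive,
decreasing-in-skill softplus link.  Tutorial levels depend only on a
multiplicative motor-skill factor, which cancels when wayfinding lengths
are normalized by tutorial lengths downstream.

Calibration
-----------
Default parameters are calibrated so that one unit of latent skill maps to
approximately one unit of the downstream WF composite (see
``docs/methods.md``), and so that a default cohort reproduces effect sizes
typical of large smartphone navigation studies: Pearson r(age, WF) ~ -0.36,
gender Hedge's g ~ 0.44, education g ~ 0.14, with the education effect
growing with age and task difficulty and heterogeneous across countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Calendar year of data collection; birth_year = DATA_COLLECTION_YEAR - age.
DATA_COLLECTION_YEAR = 2016

#: Reference age at which the education main effect is defined (mid-range).
AGE_REF = 40.0

EDUCATION4 = ("university", "college", "high-school", "no formal")

#: The four wayfinding levels entering the default WF composite.
DEFAULT_WAYFINDING_IDS = (6, 7, 8, 11)

#: Split of tertiary into university/college and of secondary-and-lower into
#: high-school/no-formal, mimicking a 42/28/27/3% four-class distribution.
_TERTIARY_SPLIT = 0.6
_SECONDARY_SPLIT = 0.9

#: (country code, relative weight, education slope offset).  Offsets emulate
#: observed cross-country heterogeneity of the education effect, from
#: near-zero-or-negative (IN) to slightly above average (RO).
DEFAULT_COUNTRIES: tuple[tuple[str, float, float], ...] = (
    ("US", 0.28, 0.0),
    ("GB", 0.17, 0.0),
    ("DE", 0.10, 0.0),
    ("FR", 0.08, 0.0),
    ("AU", 0.07, 0.0),
    ("CA", 0.07, 0.0),
    ("BR", 0.07, 0.0),
    ("NL", 0.06, 0.0),
    ("RO", 0.05, 0.02),
    ("IN", 0.05, -0.24),
)


@dataclass(frozen=True)
class ReformSpec:
    """A school-leaving-age reform acting on cohorts born from a given year.

    Parameters
    ----------
    first_affected_birth_year
        Birth year of the first cohort forced to stay in school one extra
        year (1957 for the UK 1972 reform raising the leaving age 15 -> 16).
    complier_fraction
        Fraction of would-be early leavers (secondary-and-lower education)
        whose schooling actually changed because of the reform.
    complier_skill_gain
        Latent-skill gain of compliers, in WF units (a Local Average
        Treatment Effect on the latent scale).
    """

    first_affected_birth_year: int = 1957
    complier_fraction: float = 0.25
    complier_skill_gain: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.complier_fraction <= 1.0:
            raise ValueError("complier_fraction must be in [0, 1]")
        if not np.isfinite(self.complier_skill_gain):
            raise ValueError("complier_skill_gain must be finite")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic population.

    Effects are expressed in latent WF units; with the default calibration
    the latent scale and the downstream WF composite scale approximately
    coincide.  ``beta_education`` is the tertiary-vs-lower effect at
    ``AGE_REF`` (40 years); ``beta_age_x_education`` tilts it with age.
    """

    n_participants: int = 20_000
    countries: Sequence[tuple[str, float, float]] = DEFAULT_COUNTRIES
    age_range: tuple[int, int] = (19, 70)
    prop_female: float = 0.47
    prop_tertiary_base: float = 0.70
    beta_age: float = -0.037
    beta_gender: float = 0.60
    beta_education: float = 0.18
    beta_age_x_education: float = 0.0025
    beta_difficulty_x_education: float = 0.02
    country_slope_sd: float = 0.05
    country_intercept_sd: float = 0.10
    noise_sd: float = 1.0
    motor_skill_sd: float = 0.20
    level_noise_sd: float = 1.6
    link_shift: float = 6.0
    reform: ReformSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("country_slope_sd", "country_intercept_sd", "noise_sd",
                     "motor_skill_sd", "level_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("prop_female", "prop_tertiary_base"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not self.countries:
            raise ValueError("at least one country is required")
        if any(w < 0 for _, w, _ in self.countries) or \
                sum(w for _, w, _ in self.countries) <= 0:
            raise ValueError("country weights must be non-negative, sum > 0")
        if self.reform is not None:
            self.reform.validate()


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def make_level_catalog(n_wayfinding: int, seed: int = 0) -> pd.DataFrame:
    """Build a level catalog: 2 tutorial levels plus wayfinding levels.

    Level ids follow the game's numbering: tutorials are 1 and 2; the first
    four wayfinding levels are 6, 7, 8 and 11 (the ids the WF composite
    uses); further wayfinding levels run from 12 upward.  Difficulty is
    non-decreasing in level id, mirroring a game whose levels get harder as
    the player progresses.

    Returns a DataFrame with columns
    ``level_id, is_tutorial, is_wayfinding, min_length, difficulty_param``.
    """
    if n_wayfinding < 4:
        raise ValueError(
            "n_wayfinding must be >= 4: the WF composite needs levels 6, 7, 8, 11"
        )
    rng = np.random.default_rng(seed)
    way_ids = list(DEFAULT_WAYFINDING_IDS) + list(range(12, 12 + n_wayfinding - 4))
    level_id = np.array([1, 2] + way_ids)
    is_tutorial = np.array([True, True] + [False] * n_wayfinding)
    is_wayfinding = ~is_tutorial
    min_length = np.concatenate([
        rng.uniform(500.0, 2000.0, size=2),
        rng.uniform(2000.0, 30000.0, size=n_wayfinding),
    ])
    # Difficulty grows along the level sequence: positive jittered increments.
    increments = rng.uniform(0.05, 0.25, size=n_wayfinding)
    difficulty = np.concatenate([[0.0, 0.0], 0.3 + np.cumsum(increments)])
    return pd.DataFrame({
        "level_id": level_id,
        "is_tutorial": is_tutorial,
        "is_wayfinding": is_wayfinding,
        "min_length": min_length,
        "difficulty_param": difficulty,
    })


def sample_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic participant table.

    Ages are uniform over ``age_range``; education is drawn in four classes
    with P(tertiary) = ``prop_tertiary_base``; latent skill follows

    ``beta_age*(age-40) + beta_gender*male
    + (beta_education + beta_age_x_education*(age-40) + country_slope)*tertiary
    + country_intercept + N(0, noise_sd)``

    plus, when a reform is configured, ``complier_skill_gain`` for the
    complier fraction of secondary-and-lower participants born in or after
    the first affected year.  Deterministic given ``config`` (incl. seed).

    The returned DataFrame carries the generator-only columns
    ``latent_skill`` and ``motor_skill`` (dropped when writing the public
    CSV schema) and the realized per-country effects in
    ``df.attrs["country_effects"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    codes = [c for c, _, _ in config.countries]
    weights = np.array([w for _, w, _ in config.countries], dtype=float)
    weights = weights / weights.sum()
    offsets = np.array([o for _, _, o in config.countries], dtype=float)

    country_idx = rng.choice(len(codes), size=n, p=weights)
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    male = rng.random(n) >= config.prop_female
    tertiary = rng.random(n) < config.prop_tertiary_base
    sub = rng.random(n)
    education4 = np.where(
        tertiary,
        np.where(sub < _TERTIARY_SPLIT, "university", "college"),
        np.where(sub < _SECONDARY_SPLIT, "high-school", "no formal"),
    )
    birth_year = DATA_COLLECTION_YEAR - age

    country_intercept = rng.normal(0.0, config.country_intercept_sd, size=len(codes))
    country_slope = offsets + rng.normal(0.0, config.country_slope_sd, size=len(codes))

    age_c = age - AGE_REF
    latent = (
        config.beta_age * age_c
        + config.beta_gender * male
        + (config.beta_education
           + config.beta_age_x_education * age_c
           + country_slope[country_idx]) * tertiary
        + country_intercept[country_idx]
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    if config.reform is not None:
        reform = config.reform
        early_leaver = ~tertiary
        affected = early_leaver & (birth_year >= reform.first_affected_birth_year)
        complier = affected & (rng.random(n) < reform.complier_fraction)
        latent = latent + reform.complier_skill_gain * complier

    # Folded log-normal >= 1 so trajectory lengths never undercut min_length.
    motor = np.exp(np.abs(rng.normal(0.0, config.motor_skill_sd, size=n)))

    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "age": age.astype(int),
        "gender": np.where(male, "male", "female"),
        "education4": education4,
        "country": np.array(codes, dtype=object)[country_idx],
        "birth_year": birth_year.astype(int),
        "latent_skill": latent,
        "motor_skill": motor,
    })
    df.attrs["country_effects"] = pd.DataFrame({
        "country": codes,
        "intercept": country_intercept,
        "slope_deviation": country_slope,
        "slope_total": config.beta_education + country_slope,
    })
    return df


def simulate_trajectories(
    participants: pd.DataFrame,
    levels: pd.DataFrame,
    *,
    level_noise_sd: float = 1.6,
    link_shift: float = 6.0,
    beta_difficulty_x_education: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one trajectory length per (participant, level).

    Tutorial levels:   ``length = min_length * motor_skill``.
    Wayfinding levels: ``length = min_length * motor_skill
    * (1 + difficulty_param * softplus(link_shift - skill + eps))``
    with ``eps ~ N(0, level_noise_sd)`` independent per level, and
    ``skill = latent_skill + beta_difficulty_x_education * (d_l - d_ref) *
    tertiary`` so that (when the interaction is on) the education advantage
    is amplified on harder levels.  ``d_ref`` is the mean difficulty of the
    four composite levels, keeping the WF-scale calibration untouched.

    Higher skill gives stochastically shorter wayfinding trajectories;
    every length is >= its level's ``min_length``.
    """
    if participants.empty or levels.empty:
        raise ValueError("participants and levels must be non-empty")
    rng = np.random.default_rng(seed)

    lev = levels.sort_values("level_id").reset_index(drop=True)
    way = lev[lev["is_wayfinding"]]
    tut = lev[lev["is_tutorial"]]

    core_ids = [i for i in DEFAULT_WAYFINDING_IDS if i in set(way["level_id"])]
    d_ref = float(way.set_index("level_id").loc[core_ids, "difficulty_param"].mean()) \
        if core_ids else float(way["difficulty_param"].mean())

    n = len(participants)
    motor = participants["motor_skill"].to_numpy(float)
    latent = participants["latent_skill"].to_numpy(float)
    tertiary = participants["education4"].isin(("university", "college")).to_numpy()

    frames = []
    pid = participants["participant_id"].to_numpy()

    for _, row in tut.iterrows():
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "level_id": int(row["level_id"]),
            "trajectory_length": row["min_length"] * motor,
        }))

    d = way["difficulty_param"].to_numpy(float)
    min_len = way["min_length"].to_numpy(float)
    skill = latent[:, None] + (
        beta_difficulty_x_education * (d[None, :] - d_ref) * tertiary[:, None]
    )
    eps = rng.normal(0.0, level_noise_sd, size=(n, len(way))) \
        if level_noise_sd > 0 else 0.0
    inflation = 1.0 + d[None, :] * softplus(link_shift - skill + eps)
    lengths = min_len[None, :] * motor[:, None] * inflation
    frames.append(pd.DataFrame({
        "participant_id": np.repeat(pid, len(way)),
        "level_id": np.tile(way["level_id"].to_numpy(int), n),
        "trajectory_length": lengths.ravel(),
    }))

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "level_id"]).reset_index(drop=True)


def simulate_dataset(
    config: GeneratorConfig, n_wayfinding: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (participants, trajectories, levels) from one master seed."""
    ss = np.random.SeedSequence(config.seed)
    child = [int(s.generate_state(1)[0]) for s in ss.spawn(2)]
    levels = make_level_catalog(n_wayfinding, seed=child[0])
    participants = sample_population(config)
    trajectories = simulate_trajectories(
        participants,
        levels,
        level_noise_sd=config.level_noise_sd,
        link_shift=config.link_shift,
        beta_difficulty_x_education=config.beta_difficulty_x_education,
        seed=child[1],
    )
    return participants, trajectories, levels


PARTICIPANT_COLUMNS = ["participant_id", "age", "gender", "education4",
                       "country", "birth_year"]
TRAJECTORY_COLUMNS = ["participant_id", "level_id", "trajectory_length"]
LEVEL_COLUMNS = ["level_id", "is_tutorial", "is_wayfinding", "min_length",
                 "difficulty_param"]


def write_tables(
    participants: pd.DataFrame,
    trajectories: pd.DataFrame,
    levels: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three public CSV tables (UTF-8, header row, RFC 4180)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = set(PARTICIPANT_COLUMNS) - set(participants.columns)
    if missing:
        raise SchemaError(f"participants table missing columns: {sorted(missing)}")
    paths = {
        "participants": outdir / "participants.csv",
        "trajectories": outdir / "trajectories.csv",
        "levels": outdir / "levels.csv",
    }
    participants[PARTICIPANT_COLUMNS].to_csv(paths["participants"], index=False)
    trajectories[TRAJECTORY_COLUMNS].to_csv(paths["trajectories"], index=False)
    levels[LEVEL_COLUMNS].to_csv(paths["levels"], index=False)
    return paths
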