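"""Inclusion criteria and education-class merging.

The analysis cohort keeps participants who completed enough levels for a
reliable performance estimate, entered all their demographics, are at most
70 years old, and live in countries with enough players and reasonably
balanced education classes.  Filters are applied in a single pass in that
order; country-level criteria are evaluated once on the already
age/completeness-filtered set (no fixed-point iteration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import EDUCATION4

#: 4-class -> merged 2-class mapping.  'university' and 'college' mean
#: different things in different countries, so they are pooled as tertiary;
#: 'no formal' is too small and selection-prone to analyze alone.
EDUCATION_MERGE = {
    "university": "tertiary",
    "college": "tertiary",
    "high-school": "secondary_and_lower",
    "no formal": "secondary_and_lower",
}


def merge_education(education4):
    """Map 4-level education to the merged 2-level variable.

    Accepts a single label or a pandas Series; unknown labels raise
    ``ValueError``.
    """
    if isinstance(education4, pd.Series):
        unknown = set(education4.dropna().unique()) - set(EDUCATION_MERGE)
        if unknown:
            raise ValueError(f"unknown education categories: {sorted(unknown)}")
        return education4.map(EDUCATION_MERGE)
    if education4 not in EDUCATION_MERGE:
        raise ValueError(f"unknown education category: {education4!r}")
    return EDUCATION_MERGE[education4]


@dataclass(frozen=True)
class InclusionCriteria:
    """Thresholds of the study's inclusion filter.

    ``max_age`` is inclusive ("above 70" removed, 70-year-olds kept);
    ``max_education_imbalance`` is the largest allowed ratio between the
    two merged education class sizes within a country (strictly greater
    excludes).
    """

    min_levels_completed: int = 11
    min_wayfinding_completed: int = 4
    max_age: float = 70
    min_country_n: int = 500
    max_education_imbalance: float = 10.0

    def validate(self) -> None:
        for name in ("min_levels_completed", "min_wayfinding_completed",
                     "max_age", "min_country_n", "max_education_imbalance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FilterReport:
    """Participant counts at each filtering stage plus per-country detail."""

    initial: int
    after_completeness: int
    after_age: int
    after_country: int
    per_country: pd.DataFrame = field(repr=False)

    @property
    def stages(self) -> tuple[int, int, int, int]:
        return (self.initial, self.after_completeness, self.after_age,
                self.after_country)

    def to_dict(self) -> dict:
        per_country = self.per_country.copy()
        per_country["imbalance"] = [
            None if not np.isfinite(v) else float(v)
            for v in per_country["imbalance"]
        ]
        return {
            "initial": self.initial,
            "after_completeness": self.after_completeness,
            "after_age": self.after_age,
            "after_country": self.after_country,
            "per_country": per_country.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


_REQUIRED_PARTICIPANT_COLS = ("participant_id", "age", "gender", "education4",
                              "country")


def country_eligibility(
    cohort: pd.DataFrame,
    min_country_n: int = 500,
    max_education_imbalance: float = 10.0,
) -> pd.DataFrame:
    """Per-country sample size, merged-class imbalance ratio, eligibility.

    Imbalance is max(class counts) / min(class counts) over the two merged
    classes, infinite when a class is empty.  A country is eligible iff its
    n meets the threshold and the imbalance ratio does not exceed the cap.
    """
    df = cohort.copy()
    if "education2" not in df.columns:
        df["education2"] = merge_education(df["education4"])
    rows = []
    for country, grp in df.groupby("country", sort=True):
        n_ter = int((grp["education2"] == "tertiary").sum())
        n_sec = int((grp["education2"] == "secondary_and_lower").sum())
        small, big = min(n_ter, n_sec), max(n_ter, n_sec)
        imbalance = np.inf if small == 0 else big / small
        rows.append({
            "country": country,
            "n": len(grp),
            "n_tertiary": n_ter,
            "n_secondary_and_lower": n_sec,
            "imbalance": imbalance,
            "eligible": len(grp) >= min_country_n
            and imbalance <= max_education_imbalance,
        })
    return pd.DataFrame(
        rows, columns=["country", "n", "n_tertiary", "n_secondary_and_lower",
                       "imbalance", "eligible"])


def apply_inclusion(
    participants: pd.DataFrame,
    trajectories: pd.DataFrame,
    levels: pd.DataFrame,
    criteria: InclusionCriteria | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the inclusion filter and return (cohort, report).

    Stages: (1) completeness — all demographics entered and at least
    ``min_levels_completed`` distinct levels played, of which at least
    ``min_wayfinding_completed`` wayfinding; (2) age <= ``max_age``;
    (3) country size and merged-education balance, evaluated once on the
    stage-2 survivors.  The returned cohort carries an ``education2``
    column.  Idempotent and independent of row order.
    """
    criteria = criteria or InclusionCriteria()
    criteria.validate()
    missing = set(_REQUIRED_PARTICIPANT_COLS) - set(participants.columns)
    if missing:
        raise SchemaError(f"participants table missing columns: {sorted(missing)}")
    for col in ("participant_id", "level_id"):
        if col not in trajectories.columns:
            raise SchemaError(f"trajectories table missing column: {col}")

    initial = len(participants)
    if initial == 0:
        empty = participants.copy()
        empty["education2"] = pd.Series(dtype=object)
        report = FilterReport(0, 0, 0, 0, country_eligibility(
            empty, criteria.min_country_n, criteria.max_education_imbalance))
        return empty, report

    df = participants.copy()

    # Stage 1: complete demographics + enough distinct (wayfinding) levels.
    demo_ok = df[list(_REQUIRED_PARTICIPANT_COLS)].notna().all(axis=1)
    demo_ok &= df["education4"].isin(EDUCATION4)
    wayfinding_ids = set(levels.loc[levels["is_wayfinding"], "level_id"])
    traj = trajectories.drop_duplicates(["participant_id", "level_id"])
    n_levels = traj.groupby("participant_id")["level_id"].nunique()
    n_way = (traj[traj["level_id"].isin(wayfinding_ids)]
             .groupby("participant_id")["level_id"].nunique())
    pid = df["participant_id"]
    completeness = (
        demo_ok
        & (pid.map(n_levels).fillna(0) >= criteria.min_levels_completed)
        & (pid.map(n_way).fillna(0) >= criteria.min_wayfinding_completed)
    )
    df = df[completeness]
    after_completeness = len(df)

    # Stage 2: remove participants above max_age (boundary kept).
    df = df[df["age"] <= criteria.max_age]
    after_age = len(df)

    # Stage 3: country-level criteria on the filtered set, single pass.
    df = df.copy()
    df["education2"] = merge_education(df["education4"])
    per_country = country_eligibility(
        df, criteria.min_country_n, criteria.max_education_imbalance)
    eligible = set(per_country.loc[per_country["eligible"], "country"])
    df = df[df["country"].isin(eligible)]
    after_country = len(df)

    report = FilterReport(initial, after_completeness, after_age,
                          after_country, per_country)
    return df.reset_index(drop=True), report
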