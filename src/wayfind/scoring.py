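"""Wayfinding-performance composite, training-performance control, and
per-level difficulty from trajectory lengths.

WF is the first principal component of the tutorial-normalized trajectory
lengths of a fixed set of wayfinding levels (by default 6, 7, 8 and 11),
computed on the correlation matrix (columns standardized) and oriented so
that higher WF means shorter, better trajectories.  Dividing each length by
the summed tutorial lengths removes multiplicative motor/video-gaming skill
before the composite is formed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConsistencyError, DegenerateInputError, SchemaError
from .synthetic import DEFAULT_WAYFINDING_IDS

logger = logging.getLogger(__name__)


def _tutorial_ids(levels: pd.DataFrame) -> list[int]:
    ids = levels.loc[levels["is_tutorial"], "level_id"].tolist()
    if len(ids) != 2:
        raise SchemaError(f"expected exactly 2 tutorial levels, found {len(ids)}")
    return ids


def normalize_lengths(
    trajectories: pd.DataFrame,
    levels: pd.DataFrame,
    wayfinding_ids: Sequence[int] = DEFAULT_WAYFINDING_IDS,
) -> pd.DataFrame:
    """Tutorial-normalized length matrix (rows participants, cols levels).

    Each entry is trajectory_length(level) divided by the sum of the
    participant's two tutorial trajectory lengths.  Participants missing a
    tutorial or a requested wayfinding level are dropped (count logged).
    """
    known = set(levels["level_id"])
    unknown = set(trajectories["level_id"]) - known
    if unknown:
        raise ConsistencyError(f"trajectories reference unknown levels: {sorted(unknown)}")
    missing_req = set(wayfinding_ids) - known
    if missing_req:
        raise ValueError(f"wayfinding_ids not in level catalog: {sorted(missing_req)}")

    tut = _tutorial_ids(levels)
    wide = trajectories.pivot_table(
        index="participant_id", columns="level_id",
        values="trajectory_length", aggfunc="first")
    required = tut + list(wayfinding_ids)
    present = [c for c in required if c in wide.columns]
    complete = wide[present].notna().all(axis=1) if len(present) == len(required) \
        else pd.Series(False, index=wide.index)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("normalize_lengths: dropped %d participants missing required levels",
                    dropped)
    wide = wide[complete]
    if wide.empty:
        return pd.DataFrame(columns=list(wayfinding_ids))

    tutorial_sum = wide[tut].sum(axis=1)
    if (tutorial_sum <= 0).any():
        raise DegenerateInputError("non-positive tutorial trajectory length sum")
    matrix = wide[list(wayfinding_ids)].div(tutorial_sum, axis=0)
    matrix.index.name = "participant_id"
    return matrix


def compute_wf(matrix: pd.DataFrame) -> pd.DataFrame:
    """First-PC composite of the column-standardized normalized lengths.

    Scores are the projections onto the leading eigenvector of the
    correlation matrix, sign-oriented so that corr(wf, row mean of the
    normalized lengths) < 0: large normalized lengths are poor performance,
    so higher wf = better wayfinding.  If the correlation is exactly zero
    the orientation with a positive first loading is chosen.

    Returns a DataFrame ``(participant_id, wf)``.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need at least 3 participants and 2 levels")
    X = matrix.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise DegenerateInputError("normalized length matrix contains non-finite values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError("constant column in normalized length matrix")
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z).ravel()

    row_mean = X.mean(axis=1)
    c = np.corrcoef(scores, row_mean)[0, 1]
    if c > 0 or (c == 0 and pca.components_[0, 0] < 0):
        scores = -scores
    return pd.DataFrame({"participant_id": matrix.index.to_numpy(), "wf": scores})


def training_performance(
    trajectories: pd.DataFrame, levels: pd.DataFrame
) -> pd.DataFrame:
    """Motor-skill control score from the two tutorial levels.

    tp = sum over tutorial levels of length / (cohort minimum length at
    that level); the participant(s) setting both minima score exactly 2.
    Participants missing a tutorial level are dropped (count logged).

    Returns a DataFrame ``(participant_id, tp)``.
    """
    tut = _tutorial_ids(levels)
    wide = trajectories[trajectories["level_id"].isin(tut)].pivot_table(
        index="participant_id", columns="level_id",
        values="trajectory_length", aggfunc="first")
    for t in tut:
        if t not in wide.columns:
            raise SchemaError(f"no trajectories for tutorial level {t}")
    complete = wide[tut].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("training_performance: dropped %d participants missing a tutorial",
                    dropped)
    wide = wide[complete]
    if (wide[tut] <= 0).any().any():
        raise DegenerateInputError("non-positive tutorial trajectory length")
    tp = (wide[tut] / wide[tut].min(axis=0)).sum(axis=1)
    return pd.DataFrame({"participant_id": wide.index.to_numpy(), "tp": tp.to_numpy()})


def level_difficulty(lengths_at_level: Sequence[float] | np.ndarray) -> float:
    """Difficulty of one level: (median TL - min TL) / min TL.

    With a large cohort the shortest trajectory is near-optimal, so this
    quantifies the typical excess path relative to the optimal length; the
    normalization keeps larger levels from looking artificially harder.
    Scale-invariant and >= 0, equal to 0 iff median == min.
    """
    tl = np.asarray(lengths_at_level, dtype=float)
    if tl.size == 0:
        raise ValueError("need at least one trajectory length")
    if np.any(~np.isfinite(tl)) or np.any(tl <= 0):
        raise DegenerateInputError("trajectory lengths must be positive and finite")
    m = float(np.min(tl))
    return (float(np.median(tl)) - m) / m


def difficulty_table(
    trajectories: pd.DataFrame, levels: pd.DataFrame
) -> pd.DataFrame:
    """Empirical difficulty of every wayfinding level, as a DataFrame."""
    way = set(levels.loc[levels["is_wayfinding"], "level_id"])
    rows = [
        {"level_id": lid, "difficulty": level_difficulty(grp.to_numpy())}
        for lid, grp in trajectories[trajectories["level_id"].isin(way)]
        .groupby("level_id")["trajectory_length"]
    ]
    return pd.DataFrame(rows, columns=["level_id", "difficulty"])


def per_level_scores(
    trajectories: pd.DataFrame, levels: pd.DataFrame
) -> pd.DataFrame:
    """Per-(participant, level) performance for level-clustered models.

    Each wayfinding length is divided by the participant's summed tutorial
    lengths, scaled by the level's standard deviation (putting levels on a
    common scale without removing their mean differences, which a model's
    per-level intercepts absorb), and negated, so higher = better.
    Returns a long DataFrame ``(participant_id, level_id, score)``.
    """
    tut = _tutorial_ids(levels)
    way = levels.loc[levels["is_wayfinding"], "level_id"].tolist()
    wide = trajectories.pivot_table(
        index="participant_id", columns="level_id",
        values="trajectory_length", aggfunc="first")
    complete = wide[[c for c in tut if c in wide.columns]].notna().all(axis=1) \
        if set(tut) <= set(wide.columns) else pd.Series(False, index=wide.index)
    wide = wide[complete]
    if wide.empty:
        raise DegenerateInputError("no participant has both tutorial levels")
    tutorial_sum = wide[tut].sum(axis=1)
    if (tutorial_sum <= 0).any():
        raise DegenerateInputError("non-positive tutorial trajectory length sum")
    norm = wide[[c for c in way if c in wide.columns]].div(tutorial_sum, axis=0)
    scaled = norm / norm.std(ddof=1)
    long = (-scaled).stack().rename("score").reset_index()
    long.columns = ["participant_id", "level_id", "score"]
    return long
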