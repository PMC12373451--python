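import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import wayfind as w

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def default_dataset():
    """A modest cohort under default generator settings (shared, read-only)."""
    cfg = w.GeneratorConfig(n_participants=8000, seed=42)
    participants, trajectories, levels = w.simulate_dataset(cfg, n_wayfinding=10)
    return participants, trajectories, levels


@pytest.fixture(scope="session")
def default_frame(default_dataset):
    """Filtered, scored analysis frame for the shared cohort."""
    participants, trajectories, levels = default_dataset
    criteria = w.InclusionCriteria(min_country_n=100)
    cohort, _ = w.apply_inclusion(participants, trajectories, levels, criteria)
    traj = trajectories[trajectories["participant_id"].isin(cohort["participant_id"])]
    matrix = w.normalize_lengths(traj, levels)
    frame = w.prepare_analysis_frame(cohort, w.compute_wf(matrix))
    tp = w.training_performance(traj, levels)
    return frame.merge(tp, on="participant_id")


def make_toy_levels():
    """Two tutorials (ids 1, 2) + four wayfinding levels (6, 7, 8, 11)."""
    return pd.DataFrame({
        "level_id": [1, 2, 6, 7, 8, 11],
        "is_tutorial": [True, True, False, False, False, False],
        "is_wayfinding": [False, False, True, True, True, True],
        "min_length": [10.0, 20.0, 100.0, 120.0, 140.0, 160.0],
        "difficulty_param": [0.0, 0.0, 0.4, 0.5, 0.6, 0.8],
    })


@pytest.fixture
def toy_levels():
    return make_toy_levels()


def rng_lengths(rng, pids, level_ids, base=30.0):
    rows = []
    for pid in pids:
        for lid in level_ids:
            rows.append({"participant_id": pid, "level_id": lid,
                         "trajectory_length": base * (1 + rng.random())})
    return pd.DataFrame(rows)
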