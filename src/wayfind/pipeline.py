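"""End-to-end orchestration: simulate -> filter -> score -> effects -> RDD.

One master seed is split deterministically into named substreams so that a
fixed configuration yields a byte-identical run report; every stage writes
its tables under the configured output directory and contributes to a JSON
report with stage counts, estimates and seed provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import InclusionCriteria, apply_inclusion
from .effects import (anova_main_effects, fit_random_slope_model, g_by_age_window,
                      hedges_g, prepare_analysis_frame, slopes_frame)
from .errors import SchemaError
from .rdd import placebo_rdd, pre_post_gap, sweep_cutoffs, sweep_frame
from .scoring import (compute_wf, difficulty_table, normalize_lengths,
                      per_level_scores, training_performance)
from .synthetic import (DEFAULT_WAYFINDING_IDS, GeneratorConfig, ReformSpec,
                        make_level_catalog, sample_population,
                        simulate_trajectories, write_tables)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible configuration of a full pipeline run."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    criteria: InclusionCriteria = field(default_factory=InclusionCriteria)
    wayfinding_ids: tuple[int, ...] = DEFAULT_WAYFINDING_IDS
    n_wayfinding_levels: int = 10
    run_effects: bool = True
    run_country_slopes: bool = True
    run_difficulty: bool = False
    run_rdd: bool = False
    rdd_country: str | None = "GB"
    rdd_center_year: int = 1957
    rdd_halfwidth: int = 5
    outdir: str = "wayfind_run"

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", {})
        reform = gen.pop("reform", None)
        if reform is not None:
            gen["reform"] = ReformSpec(**reform)
        if "countries" in gen:
            gen["countries"] = tuple(tuple(c) for c in gen["countries"])
        if "age_range" in gen:
            gen["age_range"] = tuple(gen["age_range"])
        crit = raw.pop("criteria", {})
        if "wayfinding_ids" in raw:
            raw["wayfinding_ids"] = tuple(raw["wayfinding_ids"])
        cfg = cls(generator=GeneratorConfig(**gen),
                  criteria=InclusionCriteria(**crit), **raw)
        if seed is not None:
            cfg.seed = seed
        if "seed" not in raw and seed is None:
            raise ValueError("a seed is required (config file or CLI flag)")
        cfg.generator = dataclasses.replace(cfg.generator, seed=cfg.seed)
        return cfg


def _substreams(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and return the run report (also written
    to ``report.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_levels, s_traj = _substreams(config.seed, 2)

    gen = dataclasses.replace(config.generator, seed=config.seed)
    report: dict = {
        "package": "wayfind",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # -- simulate ---------------------------------------------------------
    levels = make_level_catalog(config.n_wayfinding_levels, seed=s_levels)
    participants = sample_population(gen)
    trajectories = simulate_trajectories(
        participants, levels,
        level_noise_sd=gen.level_noise_sd, link_shift=gen.link_shift,
        beta_difficulty_x_education=gen.beta_difficulty_x_education, seed=s_traj)
    write_tables(participants, trajectories, levels, outdir)
    report["stages"]["simulate"] = {
        "n_participants": len(participants),
        "n_levels": len(levels),
        "n_trajectories": len(trajectories),
    }
    logger.info("simulate: %d participants, %d levels", len(participants), len(levels))

    # -- filter -----------------------------------------------------------
    cohort_df, filt = apply_inclusion(participants, trajectories, levels,
                                      config.criteria)
    filt.to_json(outdir / "filter_report.json")
    report["stages"]["filter"] = {
        "counts": list(filt.stages),
        "n_countries_retained": int(filt.per_country["eligible"].sum()),
    }
    logger.info("filter: %s", filt.stages)

    # -- score ------------------------------------------------------------
    cohort_traj = trajectories[
        trajectories["participant_id"].isin(cohort_df["participant_id"])]
    matrix = normalize_lengths(cohort_traj, levels, config.wayfinding_ids)
    wf = compute_wf(matrix)
    tp = training_performance(cohort_traj, levels)
    wf.to_csv(outdir / "wf_scores.csv", index=False)
    tp.to_csv(outdir / "training_scores.csv", index=False)
    frame = prepare_analysis_frame(cohort_df, wf).merge(tp, on="participant_id")
    report["stages"]["score"] = {
        "n_scored": len(wf),
        "wf_sd": float(wf["wf"].std(ddof=1)),
        "corr_wf_training": float(np.corrcoef(frame["wf"], frame["tp"])[0, 1]),
    }

    # -- effects ----------------------------------------------------------
    if config.run_effects:
        anova = anova_main_effects(frame)
        anova.to_csv(outdir / "anova.csv")
        gw = g_by_age_window(frame)
        gw.to_csv(outdir / "g_by_age.csv", index=False)
        ter = frame.loc[frame["education2"] == "tertiary", "wf"]
        sec = frame.loc[frame["education2"] == "secondary_and_lower", "wf"]
        overall = hedges_g(ter, sec)
        male = frame.loc[frame["gender"] == "male", "wf"]
        female = frame.loc[frame["gender"] == "female", "wf"]
        gender = hedges_g(male, female)
        report["stages"]["effects"] = {
            "education_g": overall.g,
            "education_g_ci": [overall.ci_low, overall.ci_high],
            "gender_g": gender.g,
            "age_wf_pearson_r": float(np.corrcoef(frame["age"], frame["wf"])[0, 1]),
            "anova_F": {term: float(anova.loc[term, "F"])
                        for term in anova.index if term != "Residual"},
        }
        if config.run_country_slopes and frame["country"].nunique() >= 3:
            fe, slopes = fit_random_slope_model(frame, "country")
            sf = slopes_frame(slopes)
            sf.to_csv(outdir / "country_slopes.csv", index=False)
            report["stages"]["effects"]["country_slopes"] = {
                str(r.group_id): r.slope for r in slopes}
            report["stages"]["effects"]["fixed_education"] = float(fe["tertiary"])

    # -- difficulty -------------------------------------------------------
    if config.run_difficulty:
        diff = difficulty_table(cohort_traj, levels)
        diff.to_csv(outdir / "difficulty.csv", index=False)
        long = per_level_scores(cohort_traj, levels).merge(
            frame[["participant_id", "age", "gender_male", "tertiary"]],
            on="participant_id")
        _, lvl_slopes = fit_random_slope_model(long, "level_id", outcome="score")
        ls = slopes_frame(lvl_slopes)
        ls.to_csv(outdir / "level_slopes.csv", index=False)
        merged = ls.merge(diff, left_on="group_id", right_on="level_id")
        r = float(np.corrcoef(merged["slope"], merged["difficulty"])[0, 1])
        report["stages"]["difficulty"] = {
            "n_levels": len(merged),
            "slope_difficulty_r": r,
        }

    # -- rdd --------------------------------------------------------------
    if config.run_rdd:
        sub = frame if config.rdd_country is None else \
            frame[frame["country"] == config.rdd_country]
        window = sub[(sub["birth_year"] >= config.rdd_center_year - config.rdd_halfwidth)
                     & (sub["birth_year"] <= config.rdd_center_year + config.rdd_halfwidth)]
        fits, best = sweep_cutoffs(window, config.rdd_center_year, config.rdd_halfwidth)
        sweep_frame(fits).to_csv(outdir / "rdd_sweep.csv", index=False)
        gap = pre_post_gap(window, config.rdd_center_year)
        _, placebo = placebo_rdd(window, config.rdd_center_year, config.rdd_halfwidth)
        gap_dict = {
            "cutoff": gap.cutoff, "pre_value": gap.pre_value,
            "pre_ci": list(gap.pre_ci), "post_value": gap.post_value,
            "post_ci": list(gap.post_ci), "delta_wf": gap.delta_wf,
            "sd_wf": gap.sd_wf, "iq_points": gap.iq_points,
            "n_pre": gap.n_pre, "n_post": gap.n_post,
        }
        (outdir / "gap.json").write_text(
            json.dumps(_round_floats(gap_dict), indent=2, sort_keys=True))
        report["stages"]["rdd"] = {
            "best_cutoff": best,
            "coefficient_at_best": next(
                f.coefficient for f in fits if f.cutoff == best),
            "gap": gap_dict,
            "placebo": placebo,
        }

    report = _round_floats(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def load_tables(
    participants_path: str | Path,
    trajectories_path: str | Path,
    levels_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three CSV tables.

    Checks required columns, numeric positive lengths, unique
    (participant, level) pairs, and that every trajectory references a
    catalogued level; errors name the offending column or key.
    """
    participants = pd.read_csv(participants_path)
    trajectories = pd.read_csv(trajectories_path)
    levels = pd.read_csv(levels_path)

    for name, df, cols in (
        ("participants", participants,
         ["participant_id", "age", "gender", "education4", "country"]),
        ("trajectories", trajectories,
         ["participant_id", "level_id", "trajectory_length"]),
        ("levels", levels,
         ["level_id", "is_tutorial", "is_wayfinding", "min_length"]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} table missing columns: {missing}")

    lengths = pd.to_numeric(trajectories["trajectory_length"], errors="coerce")
    bad = trajectories.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        raise SchemaError(
            f"trajectories: non-numeric or non-positive trajectory_length at "
            f"rows {bad[:5].tolist()}")
    dup = trajectories.duplicated(["participant_id", "level_id"])
    if dup.any():
        key = trajectories.loc[dup.idxmax(), ["participant_id", "level_id"]]
        raise SchemaError(
            f"trajectories: duplicate (participant_id, level_id) pair "
            f"({key['participant_id']}, {key['level_id']})")
    unknown = set(trajectories["level_id"]) - set(levels["level_id"])
    if unknown:
        raise SchemaError(f"trajectories reference unknown levels: {sorted(unknown)}")
    return participants, trajectories, levels
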