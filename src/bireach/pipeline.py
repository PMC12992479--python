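"""End-to-end orchestration: simulate -> kinematics -> kinetics -> stats.

The analysis plan mirrors a bimanual-interference experiment's results
structure: right-hand adaptation (early vs. late exposure by group),
aftereffects (late exposure vs. early washout by group), left-hand
interference on each kinematic measure, and left-hand channel wall forces at
the three movement landmarks — each a 2 (phase) x 4 (group) mixed-design
ANOVA with simple-effect one-way ANOVAs and Tukey HSD within phase — plus a
pooled-variance t-test comparing right-hand error in the visuomotor vs.
dynamic groups over the first exposure trials.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .errors import IncompleteDesignError
from .io import write_trial_tables
from .kinematics import (
    MEASURES,
    baseline_correct,
    bin_means,
    measures_table,
    phase_labels,
)
from .kinetics import channel_force_profiles, channel_forces_at_landmarks, mean_force_profile
from .simulate import TrialRecord, iter_participant_records
from .stats import MixedAnova, OneWayAnova, independent_t_test, tukey_hsd

KINETIC_MEASURES = ("force_peak", "force_ballistic", "force_end")


@dataclass(frozen=True)
class AnalysisSpec:
    """One planned 2 x 4 mixed ANOVA."""

    name: str
    measure: str          # column in the measures / landmark-force table
    hand: str
    phases: tuple[str, str]
    kind: str             # "kinematic" | "kinetic"


def default_plan() -> tuple[AnalysisSpec, ...]:
    """The ten planned mixed-design ANOVAs."""
    return (
        AnalysisSpec("right_adaptation_rmse", "rmse_bc", "R", ("early", "late"), "kinematic"),
        AnalysisSpec("right_adaptation_ide", "ide_deg_bc", "R", ("early", "late"), "kinematic"),
        AnalysisSpec("right_aftereffects_rmse", "rmse_bc", "R", ("late", "post"), "kinematic"),
        AnalysisSpec("left_interference_rmse", "rmse_bc", "L", ("early", "late"), "kinematic"),
        AnalysisSpec("left_interference_ide", "ide_deg_bc", "L", ("early", "late"), "kinematic"),
        AnalysisSpec("left_interference_iee", "iee_deg_bc", "L", ("early", "late"), "kinematic"),
        AnalysisSpec("left_interference_fee", "fee_cm_bc", "L", ("early", "late"), "kinematic"),
        AnalysisSpec("left_force_peak", "force_peak", "L", ("early", "late"), "kinetic"),
        AnalysisSpec("left_force_ballistic", "force_ballistic", "L", ("early", "late"), "kinetic"),
        AnalysisSpec("left_force_end", "force_end", "L", ("early", "late"), "kinetic"),
    )


@dataclass
class PipelineResult:
    config: ExperimentConfig
    measures: pd.DataFrame
    binned: pd.DataFrame
    anova_tables: pd.DataFrame
    posthoc: pd.DataFrame
    ttests: pd.DataFrame
    landmark_forces: pd.DataFrame
    mean_profiles: pd.DataFrame
    landmark_fractions: tuple[float, float]
    manifest: dict


# --------------------------------------------------------------------------
# Analysis helpers
# --------------------------------------------------------------------------

def _subject_phase_means(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    out = (
        df.groupby(["participant_id", "group", "phase"], sort=True, observed=True)[measure]
        .mean()
        .reset_index()
        .rename(columns={measure: "value"})
    )
    return out


def _complete_subjects(subj_means: pd.DataFrame, phases: tuple[str, str]) -> pd.DataFrame:
    """Keep only subjects with both within-subject phases (channel-trial
    placement can leave a subject without catch trials in a window)."""
    counts = subj_means.groupby("participant_id")["phase"].nunique()
    keep = counts[counts == len(phases)].index
    return subj_means[subj_means["participant_id"].isin(keep)]


def _run_one_anova(
    spec: AnalysisSpec, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the mixed ANOVA plus per-phase simple effects and Tukey HSD."""
    sub = table[table["phase"].isin(spec.phases)]
    subj = _complete_subjects(_subject_phase_means(sub, spec.measure), spec.phases)
    res = MixedAnova(subj, dv="value", between="group", within="phase", subject="participant_id").fit()
    at = res.table.reset_index()
    at.insert(0, "analysis", spec.name)
    at.insert(1, "measure", spec.measure)
    at.insert(2, "hand", spec.hand)

    ph_rows = []
    for phase in spec.phases:
        cell = subj[subj["phase"] == phase]
        ow = OneWayAnova.from_dataframe(cell, dv="value", between="group").fit()
        simple = ow.table.reset_index()
        simple["analysis"] = spec.name
        simple["measure"] = spec.measure
        simple["hand"] = spec.hand
        simple["effect"] = f"group@{phase}"
        at = pd.concat([at, simple], ignore_index=True)
        if ow.ms_error > 0:
            tk = tukey_hsd(ow.group_means, ow.ms_error, ow.df_error, ow.group_n)
            tk.insert(0, "analysis", spec.name)
            tk.insert(1, "phase", phase)
            ph_rows.append(tk)
    posthoc = pd.concat(ph_rows, ignore_index=True) if ph_rows else pd.DataFrame()
    return at, posthoc


def analyze_records(
    records: Iterable[TrialRecord],
    cfg: ExperimentConfig,
) -> PipelineResult:
    """Run the full measure-extraction + statistics battery on trial records."""
    by_participant: dict[str, list[TrialRecord]] = {}
    for rec in records:
        by_participant.setdefault(rec.participant_id, []).append(rec)
    return _analyze_stream(by_participant.values(), cfg)


def _analyze_stream(
    participant_batches: Iterable[list[TrialRecord]],
    cfg: ExperimentConfig,
    samples_dir: str | None = None,
) -> PipelineResult:
    an = cfg.analysis
    measure_frames = []
    profile_meta_frames = []
    profile_blocks = []
    first = True
    for batch in participant_batches:
        measure_frames.append(measures_table(batch))
        chan_exp = [r for r in batch if r.channel and r.block == "EXP" and r.hand == "L"]
        if chan_exp:
            meta, prof = channel_force_profiles(chan_exp)
            profile_meta_frames.append(meta)
            profile_blocks.append(prof)
        if samples_dir is not None:
            write_trial_tables(batch, samples_dir, append=not first)
        first = False

    measures = pd.concat(measure_frames, ignore_index=True)
    measures = baseline_correct(measures)
    measures["phase"] = phase_labels(measures, window=an.window_trials)
    binned = bin_means(measures, bin_size=an.bin_size)

    # landmark fractions from left-hand non-channel exposure trials
    free_left = measures[
        (measures["hand"] == "L") & (~measures["channel"]) & (measures["block"] == "EXP")
    ]
    f_peak = float(free_left["f_peak"].mean())
    f_ballistic = float(free_left["f_ballistic"].mean())

    landmark_forces = pd.DataFrame()
    mean_profiles = pd.DataFrame()
    if profile_blocks:
        prof_meta = pd.concat(profile_meta_frames, ignore_index=True)
        profiles = np.vstack(profile_blocks)
        prof_meta["phase"] = phase_labels(prof_meta, window=an.window_trials)
        forces = channel_forces_at_landmarks(profiles, f_peak, f_ballistic)
        landmark_forces = pd.concat(
            [prof_meta.reset_index(drop=True), forces.reset_index(drop=True)], axis=1
        )
        windowed = prof_meta["phase"].isin(["early", "late"]).to_numpy()
        if windowed.any():
            cells = (
                prof_meta.loc[windowed, "group"].astype(str)
                + "|"
                + prof_meta.loc[windowed, "phase"].astype(str)
            )
            mean_profiles = mean_force_profile(profiles[windowed], by=cells)
            mean_profiles[["group", "phase"]] = mean_profiles["cell"].str.split(
                "|", expand=True
            )
            mean_profiles = mean_profiles.drop(columns="cell")

    anova_frames, posthoc_frames, skipped = [], [], []
    kinematic = measures[~measures["channel"]]
    for spec in default_plan():
        if spec.kind == "kinematic":
            table = kinematic[kinematic["hand"] == spec.hand]
        else:
            if landmark_forces.empty:
                skipped.append(spec.name)
                continue
            table = landmark_forces
        try:
            at, ph = _run_one_anova(spec, table)
        except IncompleteDesignError:
            skipped.append(spec.name)
            continue
        anova_frames.append(at)
        if not ph.empty:
            posthoc_frames.append(ph)

    anova_tables = pd.concat(anova_frames, ignore_index=True)
    posthoc = pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame()

    # perturbation-magnitude check: right hand, first exposure trials
    ttests = _first_trials_ttests(kinematic, an.first_trials)

    manifest = {
        "package": "bireach",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_trials": int(len(measures)),
        "n_channel_profiles": int(sum(b.shape[0] for b in profile_blocks)),
        "landmark_fractions": {"f_peak": f_peak, "f_ballistic": f_ballistic},
        "skipped_analyses": skipped,
        "n_anova_tables": int(anova_tables["analysis"].nunique()),
    }
    return PipelineResult(
        config=cfg,
        measures=measures,
        binned=binned,
        anova_tables=anova_tables,
        posthoc=posthoc,
        ttests=ttests,
        landmark_forces=landmark_forces,
        mean_profiles=mean_profiles,
        landmark_fractions=(f_peak, f_ballistic),
        manifest=manifest,
    )


def _first_trials_ttests(kinematic: pd.DataFrame, first_trials: int) -> pd.DataFrame:
    rows = []
    early = kinematic[
        (kinematic["hand"] == "R")
        & (kinematic["block"] == "EXP")
        & (kinematic["trial"] <= first_trials)
        & (kinematic["group"].isin(["visuomotor", "dynamic"]))
    ]
    if early.empty:
        return pd.DataFrame()
    for measure in ("rmse_bc", "ide_deg_bc", "iee_deg_bc"):
        subj = early.groupby(["participant_id", "group"])[measure].mean().reset_index()
        a = subj.loc[subj["group"] == "visuomotor", measure].to_numpy()
        b = subj.loc[subj["group"] == "dynamic", measure].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        t, df, p = independent_t_test(a, b)
        rows.append(
            {"measure": measure, "contrast": "visuomotor-vs-dynamic", "t": t, "df": df, "p": p}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Entry point
# --------------------------------------------------------------------------

def run_pipeline(
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    out_dir: str | None = None,
    write_samples: bool = False,
) -> PipelineResult:
    """Simulate an experiment and run the full analysis battery.

    Deterministic given (config, seed): identical calls produce identical
    tables and manifests. Trial records are processed one participant at a
    time so the full-rate trajectories never have to be held for the whole
    experiment at once.
    """
    cfg = config if config is not None else ExperimentConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    samples_dir = out_dir if (write_samples and out_dir) else None
    stream = (recs for _, _, recs in iter_participant_records(cfg))
    result = _analyze_stream(stream, cfg, samples_dir=samples_dir)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def write_report(result: PipelineResult, out_dir: str) -> None:
    """Write all result tables, the run manifest and a Markdown summary."""
    os.makedirs(out_dir, exist_ok=True)
    result.config.to_yaml(os.path.join(out_dir, "config.yaml"))
    result.measures.to_csv(os.path.join(out_dir, "measures.csv"), index=False)
    result.binned.to_csv(os.path.join(out_dir, "binned_means.csv"), index=False)
    result.anova_tables.to_csv(os.path.join(out_dir, "anova_tables.tsv"), sep="\t", index=False)
    result.posthoc.to_csv(os.path.join(out_dir, "posthoc_tukey.tsv"), sep="\t", index=False)
    result.ttests.to_csv(os.path.join(out_dir, "ttests.tsv"), sep="\t", index=False)
    if not result.landmark_forces.empty:
        result.landmark_forces.to_csv(
            os.path.join(out_dir, "landmark_forces.csv"), index=False
        )
        result.mean_profiles.to_csv(
            os.path.join(out_dir, "mean_force_profiles.csv"), index=False
        )
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "summary.md"), "w", encoding="utf-8") as fh:
        fh.write(summary_markdown(result))


def summary_markdown(result: PipelineResult) -> str:
    """Compact human-readable summary of the run."""
    lines = [
        "# bireach analysis summary",
        "",
        f"- seed: {result.manifest['seed']}",
        f"- config hash: {result.manifest['config_hash']}",
        f"- trials analysed: {result.manifest['n_trials']}",
        f"- channel profiles: {result.manifest['n_channel_profiles']}",
        "- landmark fractions (peak velocity, ballistic end): "
        f"{result.landmark_fractions[0]:.3f}, {result.landmark_fractions[1]:.3f}",
        "",
        "## Mixed-design ANOVAs",
        "",
    ]
    cols = ["analysis", "effect", "df_num", "df_den", "F", "p", "ges"]
    lines.append(result.anova_tables[cols].to_string(index=False, float_format="%.4g"))
    if not result.ttests.empty:
        lines += ["", "## First-exposure perturbation-magnitude t-tests", ""]
        lines.append(result.ttests.to_string(index=False, float_format="%.4g"))
    if result.manifest["skipped_analyses"]:
        lines += ["", f"Skipped analyses: {result.manifest['skipped_analyses']}"]
    lines.append("")
    return "\n".join(lines)
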