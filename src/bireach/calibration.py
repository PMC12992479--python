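"""Type-I-error calibration of the interference ANOVA under a true null.

With the interlimb crosstalk gains set to zero, the left hand behaves
identically in all four groups, so the group main effect in the left-hand
RMSE mixed ANOVA is a true null: its rejection rate at alpha should match
alpha. The calibration uses a scaled-down experiment (fewer subjects and
trials, left hand only) so many replicates are affordable; the F-test is
exact under the null regardless of size, so the scaling does not change the
expected rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import (
    AnalysisConfig,
    BlockLengths,
    CrosstalkConfig,
    ExperimentConfig,
)
from .kinematics import baseline_correct, measures_table, phase_labels
from .simulate import iter_participant_records
from .stats import MixedAnova


def null_config(seed: int = 0) -> ExperimentConfig:
    """Scaled-down null experiment: crosstalk zeroed, left hand only."""
    return ExperimentConfig(
        participants_per_group=5,
        block_lengths=BlockLengths(vbl=5, kbl=5, exp=30, post=5),
        crosstalk=CrosstalkConfig(kappa_rot=0.0, kappa_dyn=0.0),
        analysis=AnalysisConfig(window_trials=10, bin_size=5, first_trials=5),
        hands=("L",),
        seed=seed,
    )


def left_rmse_group_pvalue(cfg: ExperimentConfig) -> float:
    """p-value of the group main effect in the left-hand RMSE mixed ANOVA
    (early vs. late exposure) for one simulated experiment."""
    frames = [
        measures_table(recs)
        for _, _, recs in iter_participant_records(cfg, chunk_participants=40)
    ]
    measures = baseline_correct(pd.concat(frames, ignore_index=True))
    measures["phase"] = phase_labels(measures, window=cfg.analysis.window_trials)
    sub = measures[
        (measures["hand"] == "L")
        & (~measures["channel"])
        & (measures["phase"].isin(["early", "late"]))
    ]
    subj = (
        sub.groupby(["participant_id", "group", "phase"])["rmse_bc"].mean().reset_index()
    )
    res = MixedAnova(
        subj, dv="rmse_bc", between="group", within="phase", subject="participant_id"
    ).fit()
    return float(res.table.loc["group", "p"])


def null_rejection_rate(
    n_experiments: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    config: ExperimentConfig | None = None,
) -> float:
    """Fraction of null experiments whose group effect rejects at ``alpha``."""
    base = config if config is not None else null_config()
    seeds = np.random.SeedSequence(seed).generate_state(n_experiments) % (2**31)
    hits = 0
    for s in seeds:
        cfg = dataclasses.replace(base, seed=int(s))
        if left_rmse_group_pvalue(cfg) < alpha:
            hits += 1
    return hits / n_experiments
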