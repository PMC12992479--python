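"""CSV persistence for simulated trial tables.

Two plain-text files describe an experiment: ``trials.csv`` (one row per
trial: metadata) and ``samples.csv`` (long format, one row per sample:
participant_id, hand, block, trial plus t, x, y, vx, vy, fx, fy).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import SAMPLE_COLUMNS, TrialRecord

TRIALS_FILE = "trials.csv"
SAMPLES_FILE = "samples.csv"

_KEY = ["participant_id", "hand", "block", "trial"]


def write_trial_tables(
    records: Iterable[TrialRecord], out_dir: str, append: bool = False
) -> None:
    """Write (or append) metadata and long-format sample tables."""
    os.makedirs(out_dir, exist_ok=True)
    recs = list(records)
    meta = pd.DataFrame([{**r.metadata(), "reach_distance": r.reach_distance} for r in recs])
    frames = []
    for r in recs:
        df = pd.DataFrame(r.samples, columns=list(SAMPLE_COLUMNS))
        for i, key in enumerate(_KEY):
            df.insert(i, key, getattr(r, key if key != "trial" else "trial"))
        frames.append(df)
    samples = pd.concat(frames, ignore_index=True)
    for name, df in ((TRIALS_FILE, meta), (SAMPLES_FILE, samples)):
        path = os.path.join(out_dir, name)
        header = not (append and os.path.exists(path))
        df.to_csv(path, mode="a" if append else "w", header=header, index=False)


def read_trial_tables(in_dir: str) -> list[TrialRecord]:
    """Reconstruct trial records from ``trials.csv`` + ``samples.csv``."""
    meta = pd.read_csv(os.path.join(in_dir, TRIALS_FILE))
    samples = pd.read_csv(os.path.join(in_dir, SAMPLES_FILE))
    grouped = {key: df for key, df in samples.groupby(_KEY, sort=False)}
    records = []
    for _, row in meta.iterrows():
        key = (row["participant_id"], row["hand"], row["block"], int(row["trial"]))
        arr = grouped[key][list(SAMPLE_COLUMNS)].to_numpy(dtype=float)
        records.append(
            TrialRecord(
                participant_id=row["participant_id"],
                group=row["group"],
                block=row["block"],
                trial=int(row["trial"]),
                hand=row["hand"],
                target_deg=float(row["target_deg"]),
                channel=bool(row["channel"]),
                rotation_applied_deg=float(row["rotation_applied_deg"]),
                curl_on=bool(row["curl_on"]),
                movement_time=float(row["movement_time"]),
                timing_class=row["timing_class"],
                rot_estimate=float(row["rot_estimate"]),
                dyn_estimate=float(row["dyn_estimate"]),
                aim_bias_deg=float(row["aim_bias_deg"]),
                reach_distance=float(row.get("reach_distance", 0.10)),
                samples=np.ascontiguousarray(arr),
            )
        )
    return records
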