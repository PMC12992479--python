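"""Per-trial kinematic measure extraction.

Four measures summarise each reach:

* **RMSE** — root-mean-square perpendicular deviation from the straight
  home-to-target line over the movement, normalized by the traversed path
  length (dimensionless).
* **IDE** (initial directional error) — signed angle between the
  home-to-hand (or home-to-cursor) vector and the home-to-target vector at
  peak tangential velocity; indexes feed-forward planning.
* **IEE** (initial endpoint error) — the same angle at the end of the
  initial ballistic movement (first post-peak speed local minimum or
  near-zero crossing).
* **FEE** (final endpoint error) — signed lateral displacement (cm) of the
  hand from the target once movement has ceased.

Angles and lateral displacements are counterclockwise-positive relative to
the home-to-target direction. For the 90/270 deg targets this makes
deviations into the first and third quadrants negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BinningError,
    DegenerateTrialError,
    DetectionError,
    MissingBaselineError,
    UndefinedAngleError,
)
from .simulate import TrialRecord, rotation_matrix_cw

MEASURES = ("rmse", "ide_deg", "iee_deg", "fee_cm")

#: baseline block used for correction, per hand: the left hand is corrected
#: to its kinesthetic baseline (no cursor), the right hand to its visual one.
BASELINE_BLOCK = {"L": "KBL", "R": "VBL"}


@dataclass
class ReachEvents:
    """Sample indices of the landmarks of one reach."""

    onset_idx: int
    offset_idx: int
    peak_vel_idx: int
    ballistic_end_idx: int

    def validate(self) -> None:
        if not (
            self.onset_idx
            < self.peak_vel_idx
            <= self.ballistic_end_idx
            <= self.offset_idx
        ):
            raise DetectionError(
                f"event ordering violated: onset {self.onset_idx}, peak "
                f"{self.peak_vel_idx}, ballistic {self.ballistic_end_idx}, "
                f"offset {self.offset_idx}"
            )


# --------------------------------------------------------------------------
# Event detection
# --------------------------------------------------------------------------

def detect_onset_offset(
    speed: np.ndarray,
    dt: float,
    threshold_fraction: float = 0.05,
    min_duration: float = 0.05,
    floor_fraction: float = 0.005,
) -> tuple[int, int]:
    """Locate movement onset and offset in a tangential-speed series.

    Onset: the first sample whose speed exceeds ``threshold_fraction`` of the
    peak and stays above it for ``min_duration``, then backtracked to the
    preceding near-rest sample (speed <= ``floor_fraction`` of peak), so the
    returned index sits at the true start of motion rather than at the
    threshold crossing. Offset: the last sample of the last supra-threshold
    run, extended forward to the following near-rest sample.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0 or np.nanmax(speed) <= 0:
        raise DetectionError("speed series is empty or all zero")
    peak = float(np.nanmax(speed))
    thr = threshold_fraction * peak
    floor = floor_fraction * peak
    above = speed > thr
    m = max(int(round(min_duration / dt)), 1)

    sustained = np.flatnonzero(
        np.convolve(above.astype(int), np.ones(m, dtype=int), "valid") == m
    )
    if sustained.size == 0:
        raise DetectionError("no supra-threshold run of the required duration")
    onset = int(sustained[0])
    while onset > 0 and speed[onset - 1] > floor and speed[onset - 1] <= speed[onset]:
        onset -= 1

    offset = int(np.flatnonzero(above)[-1])
    nlast = speed.size - 1
    while offset < nlast and speed[offset + 1] > floor and speed[offset + 1] <= speed[offset]:
        offset += 1
    if offset <= onset:
        raise DetectionError("offset not after onset")
    return onset, offset


def find_peak_velocity(speed: np.ndarray, onset: int, offset: int) -> int:
    """Index of maximum tangential speed on [onset, offset]; earliest on ties."""
    window = np.asarray(speed[onset : offset + 1], dtype=float)
    return onset + int(np.argmax(window))


def find_ballistic_end(
    speed: np.ndarray, peak_vel_idx: int, offset_idx: int, zero_fraction: float = 0.01
) -> int:
    """End of the initial ballistic movement.

    First index after peak velocity where speed reaches (near) zero
    (<= ``zero_fraction`` of peak speed) or is a strict local minimum (the
    start of a secondary movement); falls back to the offset if neither
    occurs.
    """
    speed = np.asarray(speed, dtype=float)
    zero_thr = zero_fraction * speed[peak_vel_idx]
    for i in range(peak_vel_idx + 1, offset_idx + 1):
        if speed[i] <= zero_thr:
            return i
        if i < offset_idx and speed[i] < speed[i - 1] and speed[i] < speed[i + 1]:
            return i
    return offset_idx


def reach_events(record_or_samples, dt: float | None = None) -> ReachEvents:
    """Detect all landmarks for one trial (record or raw samples array)."""
    samples = (
        record_or_samples.samples
        if isinstance(record_or_samples, TrialRecord)
        else np.asarray(record_or_samples)
    )
    speed = np.hypot(samples[:, 3], samples[:, 4])
    if dt is None:
        dt = float(samples[1, 0] - samples[0, 0])
    onset, offset = detect_onset_offset(speed, dt)
    peak = find_peak_velocity(speed, onset, offset)
    ball = find_ballistic_end(speed, peak, offset)
    return ReachEvents(onset, offset, peak, ball)


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def signed_angular_error(
    point: Sequence[float], home: Sequence[float], target: Sequence[float]
) -> float:
    """Signed angle (deg) between home->point and home->target.

    Counterclockwise-positive, in (-180, 180]. For forward (90 deg) and
    backward (270 deg) targets, deviations into quadrants 1 and 3 come out
    negative.
    """
    p = np.asarray(point, dtype=float) - np.asarray(home, dtype=float)
    tv = np.asarray(target, dtype=float) - np.asarray(home, dtype=float)
    if np.allclose(p, 0.0):
        raise UndefinedAngleError("point coincides with home position")
    ang = np.degrees(np.arctan2(p[1], p[0]) - np.arctan2(tv[1], tv[0]))
    ang = (ang + 180.0) % 360.0 - 180.0
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def _lateral_deviation(xy: np.ndarray, home: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Perpendicular (CCW-positive) distance of points from the home->target line."""
    tv = target - home
    t_hat = tv / np.linalg.norm(tv)
    rel = xy - home
    # z-component of t_hat x rel: positive on the counterclockwise side
    return t_hat[0] * rel[..., 1] - t_hat[1] * rel[..., 0]


def compute_rmse(
    xy: np.ndarray,
    events: ReachEvents,
    home: Sequence[float],
    target: Sequence[float],
    normalize: str = "path",
) -> float:
    """Normalized RMSE: RMS perpendicular deviation from the straight target
    vector over [onset, offset], divided by the movement length.

    ``normalize="path"`` divides by the traversed path length (default);
    ``"distance"`` divides by the straight home->target distance.
    """
    home = np.asarray(home, dtype=float)
    target = np.asarray(target, dtype=float)
    window = np.asarray(xy[events.onset_idx : events.offset_idx + 1], dtype=float)
    dev = _lateral_deviation(window, home, target)
    if normalize == "path":
        length = float(np.sum(np.linalg.norm(np.diff(window, axis=0), axis=1)))
    elif normalize == "distance":
        length = float(np.linalg.norm(target - home))
    else:
        raise ValueError("normalize must be 'path' or 'distance'")
    if length <= 0:
        raise DegenerateTrialError("zero movement length")
    return float(np.sqrt(np.mean(dev**2)) / length)


def compute_measures(
    samples: np.ndarray,
    events: ReachEvents,
    home: Sequence[float],
    target: Sequence[float],
    use_cursor: bool = False,
    rotation_deg_cw: float = 0.0,
    normalize: str = "path",
) -> dict[str, float]:
    """All four kinematic measures for one trial.

    IDE is evaluated in cursor coordinates when ``use_cursor`` is set (the
    displayed, rotated frame of the right hand during exposure); IEE and FEE
    always use hand coordinates.
    """
    home = np.asarray(home, dtype=float)
    target = np.asarray(target, dtype=float)
    xy = samples[:, 1:3]

    hand_peak = xy[events.peak_vel_idx]
    if use_cursor and rotation_deg_cw != 0.0:
        ide_point = home + rotation_matrix_cw(rotation_deg_cw) @ (hand_peak - home)
    else:
        ide_point = hand_peak

    fee_m = float(_lateral_deviation(xy[events.offset_idx], home, target))
    return {
        "rmse": compute_rmse(xy, events, home, target, normalize=normalize),
        "ide_deg": signed_angular_error(ide_point, home, target),
        "iee_deg": signed_angular_error(xy[events.ballistic_end_idx], home, target),
        "fee_cm": fee_m * 100.0,
    }


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def measures_table(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Per-trial measure table (one row per trial per hand).

    Channel trials are included and flagged; downstream kinematic analyses
    exclude them (the channel suppresses exactly the lateral deviations the
    measures quantify).
    """
    rows = []
    for rec in records:
        ev = reach_events(rec)
        meas = compute_measures(
            rec.samples,
            ev,
            rec.home,
            rec.target,
            use_cursor=rec.hand == "R" and rec.rotation_applied_deg != 0.0,
            rotation_deg_cw=rec.rotation_applied_deg,
        )
        row = rec.metadata()
        row.update(meas)
        row["f_peak"] = (ev.peak_vel_idx - ev.onset_idx) / (ev.offset_idx - ev.onset_idx)
        row["f_ballistic"] = (ev.ballistic_end_idx - ev.onset_idx) / (
            ev.offset_idx - ev.onset_idx
        )
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_correct(
    df: pd.DataFrame, measures: Sequence[str] = MEASURES
) -> pd.DataFrame:
    """Subtract each participant/hand's baseline-block mean from every trial.

    Left-hand measures are corrected to the KBL block, right-hand measures to
    the VBL block; baseline means are computed over non-channel trials.
    Corrected columns get a ``_bc`` suffix; baseline-block corrected means are
    exactly zero by construction.
    """
    df = df.copy()
    for meas in measures:
        df[f"{meas}_bc"] = np.nan
    for (pid, hand), sub in df.groupby(["participant_id", "hand"], sort=False):
        base_block = BASELINE_BLOCK[hand]
        base = sub[(sub["block"] == base_block) & (~sub["channel"])]
        if base.empty:
            raise MissingBaselineError(
                f"participant {pid} hand {hand} lacks baseline block {base_block}"
            )
        for meas in measures:
            df.loc[sub.index, f"{meas}_bc"] = sub[meas] - base[meas].mean()
    return df


def bin_means(
    df: pd.DataFrame, bin_size: int = 10, measures: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean of every measure over consecutive ``bin_size``-trial bins.

    Bins are counted within block (1-based); non-channel trials only.
    """
    if bin_size < 1:
        raise BinningError("bin_size must be >= 1")
    work = df[~df["channel"]].copy()
    for block, sub in work.groupby("block"):
        if sub["trial"].max() < bin_size:
            raise BinningError(f"block {block} shorter than one bin ({bin_size})")
    if measures is None:
        measures = [m for m in df.columns if m in MEASURES or m.endswith("_bc")]
    work["bin"] = (work["trial"] - 1) // bin_size + 1
    return (
        work.groupby(["group", "hand", "block", "bin"], sort=False)[list(measures)]
        .mean()
        .reset_index()
    )


def phase_labels(df: pd.DataFrame, window: int = 30) -> pd.Series:
    """Label each trial's analysis phase.

    ``early`` = first ``window`` exposure trials, ``late`` = last ``window``
    exposure trials, ``post`` = first ``window`` washout trials; everything
    else is unlabeled (NA).
    """
    exp_len = int(df.loc[df["block"] == "EXP", "trial"].max())
    phase = pd.Series(pd.NA, index=df.index, dtype="object")
    exp = df["block"] == "EXP"
    phase[exp & (df["trial"] <= window)] = "early"
    phase[exp & (df["trial"] > exp_len - window)] = "late"
    phase[(df["block"] == "POST") & (df["trial"] <= window)] = "post"
    return phase
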