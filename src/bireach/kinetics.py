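"""Force-channel catch-trial analysis.

On 20% of left-hand trials a stiff virtual channel constrains the hand to the
straight home-to-target line; the lateral force the hand exerts against the
channel walls exposes its intended lateral motor output, uncontaminated by
actual path deviations. Each channel reach is resampled to 1000 points on
normalized movement time, and the wall force is read at three landmarks: the
set's average relative time of peak velocity, the average relative time of
the end of the initial ballistic movement, and movement end.

Forces are counterclockwise-positive (the same convention as the kinematic
measures), so interference appears as positive wall force. Landmark fractions
are estimated from non-channel trials of the same hand, where the landmarks
are well defined; kinetic measures are not baseline-corrected.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ResamplingError
from .kinematics import ReachEvents, reach_events
from .simulate import TrialRecord


def resample_trajectory(
    samples: np.ndarray, onset: int, offset: int, n: int = 1000
) -> np.ndarray:
    """Linear interpolation of the samples onto ``n`` points of normalized
    movement time over [onset, offset]; endpoints are preserved exactly.

    Returns an (n, columns) array with the same columns as the input, the
    time column replaced by normalized time in [0, 1].
    """
    window = np.asarray(samples[onset : offset + 1], dtype=float)
    if window.shape[0] < 2:
        raise ResamplingError("need at least 2 samples between onset and offset")
    t = window[:, 0]
    u_src = (t - t[0]) / (t[-1] - t[0])
    u_new = np.linspace(0.0, 1.0, n)
    out = np.empty((n, window.shape[1]))
    out[:, 0] = u_new
    for c in range(1, window.shape[1]):
        out[:, c] = np.interp(u_new, u_src, window[:, c])
    return out


def landmark_fractions(events: Iterable[ReachEvents]) -> tuple[float, float]:
    """Mean relative times of peak velocity and ballistic end over a trial set.

    Each trial contributes (event_idx - onset_idx) / (offset_idx - onset_idx).
    """
    f_peak, f_ball = [], []
    for ev in events:
        span = ev.offset_idx - ev.onset_idx
        f_peak.append((ev.peak_vel_idx - ev.onset_idx) / span)
        f_ball.append((ev.ballistic_end_idx - ev.onset_idx) / span)
    if not f_peak:
        raise InvalidParameterError("empty trial set")
    return float(np.mean(f_peak)), float(np.mean(f_ball))


def lateral_force_against_wall(record: TrialRecord) -> np.ndarray:
    """Per-sample force the hand applies against the channel wall (N).

    The recorded (fx, fy) is the wall's restoring force on the hand; its
    negative, projected on the counterclockwise-perpendicular of the target
    line, is the participant's push, CCW-positive.
    """
    th = np.radians(record.target_deg)
    nvec = np.array([-np.sin(th), np.cos(th)])
    return -(record.samples[:, 5] * nvec[0] + record.samples[:, 6] * nvec[1])


def channel_force_profiles(
    records: Iterable[TrialRecord], n: int = 1000
) -> tuple[pd.DataFrame, np.ndarray]:
    """1000-point lateral wall-force profiles for a set of channel trials.

    Returns (metadata frame, profile matrix of shape (n_trials, n)).
    """
    meta_rows, profiles = [], []
    for rec in records:
        if not rec.channel:
            continue
        ev = reach_events(rec)
        lat = lateral_force_against_wall(rec)
        cols = np.column_stack([rec.samples[:, 0], lat])
        res = resample_trajectory(cols, ev.onset_idx, ev.offset_idx, n=n)
        profiles.append(res[:, 1])
        meta_rows.append(rec.metadata())
    if not profiles:
        raise InvalidParameterError("no channel trials in the record set")
    return pd.DataFrame(meta_rows), np.vstack(profiles)


def channel_forces_at_landmarks(
    profiles: np.ndarray, f_peak: float, f_ballistic: float
) -> pd.DataFrame:
    """Per-trial wall force at the three landmark fractions (and movement end).

    The force is read from the 1000-point profile at index round(f * (n-1)).
    """
    profiles = np.atleast_2d(profiles)
    n = profiles.shape[1]
    out = {}
    for name, frac in (("force_peak", f_peak), ("force_ballistic", f_ballistic), ("force_end", 1.0)):
        if not 0.0 < frac <= 1.0:
            raise InvalidParameterError(f"landmark fraction {frac} outside (0, 1]")
        out[name] = profiles[:, int(round(frac * (n - 1)))]
    return pd.DataFrame(out)


def mean_force_profile(
    profiles: np.ndarray, by: Sequence | pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pointwise mean and SD of force profiles, optionally per group cell.

    ``by`` may be a sequence of cell labels (one per profile row) or None for
    a single cell. Returns a long frame (cell, u, mean, sd); sd is 0 for
    single-profile cells.
    """
    profiles = np.atleast_2d(profiles)
    n_trials, n = profiles.shape
    u = np.linspace(0.0, 1.0, n)
    labels = pd.Series(["all"] * n_trials) if by is None else pd.Series(list(by))
    frames = []
    for cell, idx in labels.groupby(labels).groups.items():
        block = profiles[np.asarray(idx)]
        if block.shape[0] == 0:
            raise InvalidParameterError(f"empty profile cell {cell}")
        frames.append(
            pd.DataFrame(
                {
                    "cell": cell,
                    "u": u,
                    "mean": block.mean(axis=0),
                    "sd": block.std(axis=0, ddof=0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
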