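"""Parameter-recovery utilities.

Two sanity checks that close the loop between the generator and the analysis:

* recover the force-channel wall stiffness (N/cm) from simulated quasi-static
  wall presses, and
* recover the state-space learner's retention and learning rate from the
  right hand's trial-by-trial directional-error curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ChannelConfig
from .errors import InvalidParameterError
from .simulate import channel_wall_force


def recover_channel_stiffness(
    depths_m,
    channel: ChannelConfig | None = None,
    ramp_factor: float = 1.0,
) -> float:
    """Least-squares slope (N/cm) of wall force vs. quasi-static penetration.

    The hand is held at each penetration depth beyond the wall with zero
    lateral velocity; the recorded restoring-force magnitudes are regressed
    on depth. With the default channel, the slope is the programmed 20 N/cm.
    """
    ch = channel if channel is not None else ChannelConfig()
    depths = np.asarray(depths_m, dtype=float)
    if depths.size < 2 or np.unique(depths).size < 2:
        raise InvalidParameterError("need at least two distinct penetration depths")
    forces = np.array(
        [
            abs(
                channel_wall_force(
                    ch.half_width + d, 0.0, ch.stiffness, ch.half_width, ch.damping,
                    ramp_factor,
                )
            )
            for d in depths
        ]
    )
    slope_n_per_m = float(np.polyfit(depths, forces, 1)[0])
    return slope_n_per_m / 100.0


@dataclass
class LearningRateRecovery:
    retention: float
    rate: float
    identifiable: bool


def recover_learning_rate(
    error_curves: np.ndarray,
    perturbation_magnitude: float,
) -> LearningRateRecovery:
    """Fit the single-rate learner to exposure-phase error curves.

    ``error_curves`` is (n_participants, n_trials) — or 1-D for a single
    participant — of per-trial errors e_n = perturbation - estimate (e.g. the
    magnitude of cursor IDE during exposure to a rotation). Under the
    generator, e_{n+1} = R*(1-a) + (a-b)*e_n with R the perturbation
    magnitude, so a linear regression of e_{n+1} on e_n on the
    participant-averaged curve identifies retention a and rate b.

    A flat curve (no learning signal) is flagged non-identifiable.
    """
    curves = np.atleast_2d(np.asarray(error_curves, dtype=float))
    if curves.shape[1] < 50:
        raise InvalidParameterError("need at least 50 exposure trials")
    if perturbation_magnitude == 0:
        raise InvalidParameterError("perturbation magnitude must be non-zero")
    curve = curves.mean(axis=0)
    spread = float(np.std(curve))
    if spread < max(1e-9, 0.02 * abs(perturbation_magnitude)):
        return LearningRateRecovery(np.nan, np.nan, identifiable=False)
    slope, intercept = np.polyfit(curve[:-1], curve[1:], 1)
    retention = 1.0 - intercept / perturbation_magnitude
    rate = retention - slope
    return LearningRateRecovery(float(retention), float(rate), identifiable=True)
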