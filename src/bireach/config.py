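"""Experiment configuration.

The configuration mirrors the four-group bimanual reaching study the package
emulates: two baseline blocks (visual, kinesthetic), a 250-trial exposure block
in which the right hand is perturbed (45 deg clockwise cursor rotation and/or a
20 N.s/m velocity-dependent curl field, by group), and a 50-trial washout
block. The left hand loses its cursor from the kinesthetic baseline onward and
receives a stiff force channel on 20% of trials.

All internal units are SI (m, s, N); angles are degrees at this boundary and
converted to radians inside the simulator. Counterclockwise is positive for
angles and lateral displacements throughout the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import InvalidParameterError

GROUPS = ("control", "visuomotor", "dynamic", "combined")
BLOCKS = ("VBL", "KBL", "EXP", "POST")
HANDS = ("L", "R")


@dataclass
class BlockLengths:
    vbl: int = 30
    kbl: int = 30
    exp: int = 250
    post: int = 50

    def as_dict(self) -> dict[str, int]:
        return {"VBL": self.vbl, "KBL": self.kbl, "EXP": self.exp, "POST": self.post}


@dataclass
class ChannelConfig:
    """Force-channel (catch-trial) mechanics.

    stiffness: wall spring constant, N/m (2000 N/m = 20 N/cm).
    half_width: half the channel width, m (0.25 mm total width).
    damping: lateral viscous coefficient, N.s/m, active between and outside
        the walls so wall-to-wall oscillations are damped.
    ramp_s: duration of the pre-movement ramp of the wall gains; the ramp
        completes while the hand holds at home, so it is fully on (factor 1)
        during the reach.
    """

    stiffness: float = 2000.0
    half_width: float = 0.000125
    damping: float = 5.0
    ramp_s: float = 1.5


@dataclass
class AdaptationConfig:
    """Single-rate state-space learner parameters, per perturbation modality.

    The internal estimate x follows x' = retention * x + rate * error.
    Defaults give ~90% asymptotic compensation within the 250-trial exposure.
    """

    retention_rot: float = 0.99
    rate_rot: float = 0.10
    retention_dyn: float = 0.99
    rate_dyn: float = 0.08


@dataclass
class CrosstalkConfig:
    """Interlimb crosstalk: left-hand aim bias driven by right-hand adaptation.

    bias_deg = kappa_rot * rot_estimate_deg
             + kappa_dyn * dyn_estimate * bias_scale_dyn

    Counterclockwise-positive, so interference appears as a counterclockwise
    bias of the left hand. ``bias_scale_dyn`` converts the dimensionless
    fraction of curl gain compensated into a degree-equivalent drive.
    """

    kappa_rot: float = 0.15
    kappa_dyn: float = 0.06
    bias_scale_dyn: float = 45.0


@dataclass
class NoiseConfig:
    """Execution/sensor noise. The *_novision values apply to the left hand
    once its cursor is removed (KBL onward)."""

    aim_sd_deg: float = 1.5
    aim_sd_deg_novision: float = 2.5
    endpoint_sd_m: float = 0.002
    endpoint_sd_m_novision: float = 0.004
    sensor_sd_N: float = 0.05

    def silent(self) -> "NoiseConfig":
        return NoiseConfig(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class ControllerConfig:
    """PD tracking of a minimum-jerk reference by a point-mass hand."""

    kp: float = 800.0
    kd: float = 40.0
    mass: float = 1.0


@dataclass
class TimingConfig:
    """Per-trial commanded movement duration, s. Durations are drawn from a
    clipped normal so most trials land in the rewarded 300-450 ms window."""

    mean_s: float = 0.375
    sd_s: float = 0.040
    min_s: float = 0.250
    max_s: float = 0.550
    settle_s: float = 0.300


@dataclass
class AnalysisConfig:
    """Windows used by the analysis pipeline."""

    window_trials: int = 30   # early/late exposure and post-exposure windows
    bin_size: int = 10
    first_trials: int = 10    # right-hand perturbation-magnitude t-test window


@dataclass
class ExperimentConfig:
    participants_per_group: int = 15
    block_lengths: BlockLengths = field(default_factory=BlockLengths)
    reach_distance: float = 0.10
    target_angles: tuple[float, float] = (90.0, 270.0)
    dt: float = 0.001
    movement_window: tuple[float, float] = (0.300, 0.450)
    rotation_deg: float = 45.0
    curl_gain: float = 20.0
    curl_sense: str = "CW"
    channel: ChannelConfig = field(default_factory=ChannelConfig)
    channel_fraction: float = 0.20
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    crosstalk: CrosstalkConfig = field(default_factory=CrosstalkConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_decimation: int = 5
    hands: tuple[str, ...] = ("L", "R")
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bl = self.block_lengths
        if min(bl.vbl, bl.kbl, bl.exp, bl.post) <= 0:
            raise InvalidParameterError("all block lengths must be positive")
        if not 0.0 <= self.channel_fraction <= 1.0:
            raise InvalidParameterError("channel_fraction must be in [0, 1]")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.reach_distance <= 0:
            raise InvalidParameterError("reach_distance must be positive")
        if self.participants_per_group <= 0:
            raise InvalidParameterError("participants_per_group must be positive")
        if self.curl_gain < 0:
            raise InvalidParameterError("curl_gain must be non-negative")
        if self.curl_sense not in ("CW", "CCW"):
            raise InvalidParameterError("curl_sense must be 'CW' or 'CCW'")
        if self.channel.stiffness < 0 or self.channel.damping < 0:
            raise InvalidParameterError("channel stiffness/damping must be non-negative")
        ad = self.adaptation
        for name in ("retention_rot", "rate_rot", "retention_dyn", "rate_dyn"):
            v = getattr(ad, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"adaptation.{name} must be in [0, 1]")
        if self.crosstalk.kappa_rot < 0 or self.crosstalk.kappa_dyn < 0:
            raise InvalidParameterError("crosstalk gains must be non-negative")
        if self.output_decimation < 1:
            raise InvalidParameterError("output_decimation must be >= 1")
        if any(h not in HANDS for h in self.hands) or not self.hands:
            raise InvalidParameterError("hands must be a non-empty subset of ('L', 'R')")

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        sub = {
            "block_lengths": BlockLengths,
            "channel": ChannelConfig,
            "adaptation": AdaptationConfig,
            "crosstalk": CrosstalkConfig,
            "noise": NoiseConfig,
            "controller": ControllerConfig,
            "timing": TimingConfig,
            "analysis": AnalysisConfig,
        }
        for key, klass in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        for key in ("target_angles", "movement_window", "hands"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
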