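import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from bireach import (  # noqa: E402
    AnalysisConfig,
    BlockLengths,
    ExperimentConfig,
)


@pytest.fixture(scope="session")
def small_config() -> ExperimentConfig:
    """A scaled-down experiment that keeps the full block structure."""
    return ExperimentConfig(
        participants_per_group=3,
        block_lengths=BlockLengths(vbl=6, kbl=6, exp=50, post=10),
        channel_fraction=0.3,
        analysis=AnalysisConfig(window_trials=10, bin_size=5, first_trials=5),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_config() -> ExperimentConfig:
    """Smallest config that still exercises every block."""
    return ExperimentConfig(
        participants_per_group=2,
        block_lengths=BlockLengths(vbl=4, kbl=4, exp=10, post=4),
        channel_fraction=0.25,
        analysis=AnalysisConfig(window_trials=4, bin_size=2, first_trials=2),
        seed=11,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
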