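import numpy as np
import pytest

from deskbreak import AlgorithmConfig


@pytest.fixture
def config() -> AlgorithmConfig:
    return AlgorithmConfig()


@pytest.fixture
def small_config() -> AlgorithmConfig:
    """Scaled-down thresholds so short strings exercise every rule."""
    return AlgorithmConfig(
        invalid_run_epochs=3,
        min_ambulatory_epochs=2,
        valid_day_min_valid_minutes=1.0,
        valid_day_max_invalid_minutes=1.0,
        amber_start_minutes=0.75,
        red_start_minutes=1.0,
        flash_start_minutes=1.25,
        prolonged_bout_minutes=1.0,
        compliance_latency_minutes=0.75,
        latency_bin_edges_minutes=(0.25, 0.5, 0.75),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
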