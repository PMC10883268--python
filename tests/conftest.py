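import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from secgate import (BurstSearchParams, SimConfig, estimate_background,
                     search_bursts, simulate_measurement)

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def apo_data():
    """One mid-size apo measurement shared across unit tests."""
    cfg = SimConfig(orientation_weight=0.0, acquisition_duration_s=60.0,
                    seed=11)
    return simulate_measurement(cfg)


@pytest.fixture(scope="session")
def apo_background(apo_data):
    return estimate_background(apo_data)


@pytest.fixture(scope="session")
def apo_bursts(apo_data, apo_background):
    return search_bursts(apo_data, apo_background,
                         BurstSearchParams(channels="all"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
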