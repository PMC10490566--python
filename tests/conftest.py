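import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mabumat as mm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> mm.SensorConfig:
    return mm.SensorConfig()


@pytest.fixture(scope="session")
def thresholds() -> mm.ValidationThresholds:
    return mm.ValidationThresholds()


@pytest.fixture(scope="session")
def beta() -> mm.FilterParams:
    return mm.FilterParams()


@pytest.fixture(scope="session")
def ideal_frame(config, beta) -> mm.PressureFrame:
    """Noise-free, filtered frame of a textbook wide stance."""
    frame, _ = mm.synth_frame(mm.StanceSpec(noise_sd=0.0), config)
    return mm.filter_frame(frame, beta)


@pytest.fixture(scope="session")
def ideal_profile(ideal_frame, thresholds, config) -> mm.CalibrationProfile:
    return mm.calibrate(ideal_frame, thresholds, config)


def random_frame(rng: np.random.Generator, n_rows: int, n_cols: int,
                 max_value: int = 4095) -> mm.PressureFrame:
    return mm.PressureFrame(rng.integers(0, max_value + 1, size=(n_rows, n_cols)))
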