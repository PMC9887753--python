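import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from catrace import AnalysisParams, SimConfig, simulate_trace

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_cfg():
    """Noiseless config with every stimulus and transient peak on the sample grid.

    frame_rate 100 with time_to_peak 0.05 and stimuli at odd integer seconds
    puts onsets and peaks exactly on samples, so amplitudes are exact.
    """
    return SimConfig(frame_rate=100.0, noise_sd=0.0, amplitude_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def short_cfg():
    """Short noiseless grid-aligned protocol for fast unit tests."""
    return SimConfig(
        frame_rate=100.0, noise_sd=0.0, amplitude_cv=0.0, seed=0,
        paced_duration=21.0, pause_duration=8.0, caffeine_duration=8.0,
    )


@pytest.fixture(scope="session")
def short_trace(short_cfg):
    return simulate_trace(short_cfg)


@pytest.fixture()
def params():
    return AnalysisParams(rng_seed=1234)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
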