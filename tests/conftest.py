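import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dualgait.config import PipelineConfig
from dualgait.pipeline import extract_strides
from dualgait.synth import CI_PROFILE, CONTROL_PROFILE, simulate_walk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: sensor rendering with no noise, no bias and identity mounting — the
#: configuration used for ground-truth recovery checks
CLEAN = dict(
    noise_accel=0.0,
    noise_gyro=0.0,
    accel_bias_sd=0.0,
    gyro_bias_sd=0.0,
    mounting=None,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_walk():
    """One noiseless two-foot walk (10 strides/foot) with ground truth."""
    recs, truth = simulate_walk(
        CONTROL_PROFILE, "single", n_strides=10, seed=2, **CLEAN
    )
    return recs, truth


@pytest.fixture(scope="session")
def clean_records(clean_walk, config):
    """Retained stride records per foot for the noiseless walk."""
    recs, truth = clean_walk
    return {foot: extract_strides(recs[foot], config) for foot in recs}, truth


@pytest.fixture(scope="session")
def noisy_walk():
    """A dual-task walk with default noise, biases and random mounting."""
    recs, truth = simulate_walk(CI_PROFILE, "dual", n_strides=10, seed=3)
    return recs, truth
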