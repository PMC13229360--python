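import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fgakit import GaitParams, simulate_walk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> GaitParams:
    return GaitParams(step_length=0.6, step_width=0.10, cadence=2.0,
                      walk_distance=6.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_walk(default_params):
    """One noiseless 6 m walk with its ground truth."""
    return simulate_walk(default_params)
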