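import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from surgskill.presets import default_profiles
from surgskill.simulate import generate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="sample of n=")
        yield


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def novice_trial(profiles):
    trial, truth = generate_trial(profiles["novice"], "N01", 1, seed=42)
    return trial, truth


@pytest.fixture(scope="session")
def intermediate_trial(profiles):
    trial, truth = generate_trial(profiles["intermediate"], "I01", 1, seed=43)
    return trial, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
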