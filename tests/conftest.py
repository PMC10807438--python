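import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microniche import plates, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_truth():
    """16-strain community truth with zero measurement noise."""
    return simulate.default_community_truth(seed=11, blank_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_plates(noiseless_truth):
    return simulate.generate_plate_set(noiseless_truth)


@pytest.fixture(scope="session")
def noiseless_calls(noiseless_truth, noiseless_plates):
    corrected = plates.correct_absorbance(noiseless_plates)
    return plates.score_growth(corrected)


@pytest.fixture(scope="session")
def noisy_truth():
    """Default (noisy, strong-signal) community truth."""
    return simulate.default_community_truth(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
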