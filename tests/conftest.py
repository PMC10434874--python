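import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth():
    """Ground-truth Lennard-Jones potential of the validation scenarios."""
    from pairforce.validation import default_truth

    return default_truth()


@pytest.fixture(scope="session")
def small_steady_dataset():
    """A short fluctuating steady-state recording shared across tests."""
    from pairforce.validation import generate, make_scenario

    return generate(make_scenario("steady_state", seed=7, total_time=30.0,
                                  relax_time=30.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
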