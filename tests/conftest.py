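import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vaconcord.simulate import generate, kilifi_default_spec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return generate(kilifi_default_spec(seed=20140422))


@pytest.fixture(scope="session")
def large_sim():
    """A large cohort for Monte-Carlo recovery checks."""
    return generate(kilifi_default_spec(seed=20140422, n_deaths=5000))


@pytest.fixture
def rng():
    return np.random.default_rng(20140422)
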