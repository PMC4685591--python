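import pytest
from hypothesis import HealthCheck, settings

from crownsim import SweepSpec, run_diversification, run_equal_rates

settings.register_profile(
    "crownsim",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("crownsim")

#: Seed used for every stochastic check in the suite.
TEST_SEED = 11


@pytest.fixture(scope="session")
def equal_rates_result():
    """The full critical sweep (S = E in 0.1..0.9, T = 114, 50 survivors each)."""
    return run_equal_rates(SweepSpec(mode="equal_rates", seed=TEST_SEED))


@pytest.fixture(scope="session")
def diversification_result():
    """The full supercritical sweep (E x D grid, T = 15, 50 survivors each)."""
    return run_diversification(SweepSpec(mode="diversification", seed=TEST_SEED))
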