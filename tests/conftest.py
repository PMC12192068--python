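import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from siirr.effects import scenario_registry  # noqa: E402
from siirr.simulate import integrate  # noqa: E402


@pytest.fixture(scope="session")
def registry():
    return scenario_registry()


@pytest.fixture(scope="session")
def fig1_traj(registry):
    """The basic I1(0) >> I2(0) case, integrated once per session."""
    return integrate(registry["fig1_base"])


@pytest.fixture(scope="session")
def fig9_traj(registry):
    """The basic I1(0) = I2(0) case, integrated once per session."""
    return integrate(registry["fig9_base"])
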