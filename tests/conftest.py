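import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecothresh import default_foodweb, make_model, rescale_pressure
from ecothresh.synthetic import FISHING_MULTIPLIERS, GradientDesign, simulate_gradient

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fishing_pressures():
    """The 15 fishing multipliers (0-10x baseline) on the [0, 1] axis."""
    return rescale_pressure(np.asarray(FISHING_MULTIPLIERS))


@pytest.fixture(scope="session")
def shannon_fishing_model():
    """Best-fit broken-stick for Shannon diversity under fishing."""
    return make_model("piecewise", 0.33, 1.37, -5.58, -1.22)


@pytest.fixture(scope="session")
def resilience_habitat_model():
    """Best-fit sigmoid for resilience under nearshore habitat pressure."""
    return make_model("sigmoidal", 1.34, 0.007, 0.004, 13.39)


@pytest.fixture(scope="session")
def sablefish_fishing_model():
    """Best-fit negative exponential for sablefish biomass vs fishing."""
    return make_model("negexp", -0.03, 0.52, -3.15)


@pytest.fixture(scope="session")
def default_spec():
    return default_foodweb()


@pytest.fixture(scope="session")
def fishing_gradient(default_spec):
    """Deterministic fishing-gradient run of the shipped food web
    (session-scoped: several tests read from it)."""
    return simulate_gradient(default_spec, GradientDesign("fishing"))
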