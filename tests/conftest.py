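import pytest
from hypothesis import HealthCheck, settings

from chayenergy import fig1_defaults, simulate, standard_initial_state

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return fig1_defaults()


@pytest.fixture(scope="session")
def attractor(params):
    return standard_initial_state(params)


@pytest.fixture(scope="session")
def spont_traj(params, attractor):
    """The headline 30 s spontaneous run on the default output grid."""
    return simulate(params, duration=30.0, init=attractor)


@pytest.fixture(scope="session")
def fine_traj(params, attractor):
    """A 6 s spontaneous run recorded on the integration grid.

    Long enough to contain the first complete steady-state burst; used for
    landmark analyses that probe the near-balance of currents at the spike
    peak.
    """
    return simulate(params, duration=6.0, init=attractor, record_stride=1)
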