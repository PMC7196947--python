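import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from revlearn import PriorSpec, Session, TaskConfig, simulate_session
from revlearn.inference import GridAxis
from revlearn.models import Params

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def priors() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def coarse_priors() -> PriorSpec:
    """Small grids for fast fits in structural tests."""
    rate = GridAxis(0.05, 0.95, 10)
    return PriorSpec(grids={
        "alpha": rate, "alpha_pos": rate, "alpha_neg": rate, "eta": rate,
        "pi": GridAxis(-1.0, 2.0, 7), "beta": GridAxis(0.0, 8.0, 9),
    })


@pytest.fixture(scope="session")
def rw3_params() -> Params:
    return Params(alpha_pos=0.6, alpha_neg=0.4, pi=0.8, beta=2.0)


@pytest.fixture(scope="session")
def rw3_session(rw3_params) -> Session:
    return simulate_session("RW3", rw3_params, TaskConfig(n_trials=200), seed=11)


@pytest.fixture(scope="session")
def short_session(rw3_params) -> Session:
    return simulate_session("RW3", rw3_params, TaskConfig(n_trials=10), seed=5)


def make_session(choices, outcomes, high_sides=None, **kw) -> Session:
    """Hand-build a session; high side defaults to left throughout."""
    choices = np.asarray(choices)
    if high_sides is None:
        high_sides = np.zeros_like(choices)
    return Session(choices=choices, high_sides=np.asarray(high_sides),
                   outcomes=np.asarray(outcomes), **kw)


@pytest.fixture(scope="session")
def random_sessions() -> list[Session]:
    """A bank of RANDOM-agent sessions for identity checks."""
    return [simulate_session("RANDOM", Params(), TaskConfig(n_trials=50), seed=s)
            for s in range(100)]
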