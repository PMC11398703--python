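import numpy as np
import pytest

from distgame import casa20, casa20_complete_schedule, casa20_free_schedule
from distgame.network import generate_small_world


@pytest.fixture(scope="session")
def casa():
    return casa20()


@pytest.fixture(scope="session")
def complete_schedule():
    return casa20_complete_schedule()


@pytest.fixture(scope="session")
def free_schedule():
    return casa20_free_schedule()


@pytest.fixture(scope="session")
def small_net():
    """A small-world network small enough for fast unit tests."""
    return generate_small_world(200, 6, 0.3, seed=7)


@pytest.fixture(scope="session")
def net500():
    """The reference-size test network for simulation checks."""
    return generate_small_world(500, 6, 0.3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def random_simplex(rng, n, size=None):
    """Uniformly distributed points on the n-simplex."""
    return rng.dirichlet(np.ones(n), size=size)
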