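import numpy as np
import pytest

from iitcalc import condition_on_background
from iitcalc.fixtures import abc_network, copy_loop, photodiode, random_network


@pytest.fixture(scope="session")
def abc():
    net, state = abc_network()
    return net, state


@pytest.fixture(scope="session")
def abc_cs(abc):
    net, state = abc
    return condition_on_background(net, net.labels, state)


@pytest.fixture(scope="session")
def photodiode_cs():
    net, state, subset = photodiode()
    return condition_on_background(net, subset, state)


@pytest.fixture(scope="session")
def copy_ring_cs():
    net, state = copy_loop(4)
    return condition_on_background(net, net.labels, state)


@pytest.fixture(scope="session")
def random_nets():
    """A frozen sample of deterministic generator networks for property tests."""
    return [random_network(seed, n=3) for seed in range(12)] + [
        random_network(seed, n=4) for seed in (100, 101, 102)
    ]


def random_distribution(rng: np.random.Generator, n_states: int) -> np.ndarray:
    """Random dyadic-ish distribution over n_states states."""
    weights = rng.integers(0, 8, size=n_states).astype(float)
    if weights.sum() == 0:
        weights[int(rng.integers(n_states))] = 1.0
    return weights / weights.sum()
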