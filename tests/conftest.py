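import numpy as np
import pytest

from ergokit import build_fixture
from ergokit.network import ReactionNetwork


@pytest.fixture
def birth_death():
    return build_fixture("birth_death")


@pytest.fixture
def dimerization():
    return build_fixture("dimerization_29")


@pytest.fixture
def sir():
    return build_fixture("sir_37")


@pytest.fixture
def conversion():
    """Closed conversion network S1 <-> S2 (mass conserved)."""
    net = ReactionNetwork(["S1", "S2"], name="conversion")
    net.add_reaction("fwd", {"S1": 1}, {"S2": 1}, 1.0)
    net.add_reaction("bwd", {"S2": 1}, {"S1": 1}, 2.0)
    return net


@pytest.fixture
def chain():
    """0 ->(6) S1 ->(2) S2 ->(3) 0."""
    net = ReactionNetwork(["S1", "S2"], name="chain")
    net.add_reaction("b", {}, {"S1": 1}, 6.0)
    net.add_reaction("c", {"S1": 1}, {"S2": 1}, 2.0)
    net.add_reaction("d", {"S2": 1}, {}, 3.0)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240626)


def poisson_pmf(lam, n):
    """Poisson(lam) probabilities for 0..n-1 (oracle for birth-death)."""
    import math

    return np.array([math.exp(-lam) * lam**k / math.factorial(k) for k in range(n)])
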