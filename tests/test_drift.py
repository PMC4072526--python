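"""Drift decomposition, diffusivity, conservation cone, Condition DD."""

import itertools
import math

import numpy as np
import pytest

from ergokit import (
    build_fixture,
    conservation_vector,
    diffusivity,
    drift_vector,
    evaluate_propensities,
    quadratic_drift,
    unimolecular_affine,
    verify_dd,
)
from ergokit.drift import audit_certificate
from ergokit.fixtures import random_mass_action_network
from ergokit.network import ReactionNetwork


def falling_factorial_oracle(x, m):
    """Count ordered reactant tuples by brute enumeration / m!."""
    count = 0
    for tup in itertools.permutations(range(int(x)), m):
        count += 1
    return count / math.factorial(m)


@pytest.mark.parametrize("x, m", [(4, 2), (3, 3), (5, 1), (2, 3), (0, 2)])
def test_mass_action_combinatorics_against_enumeration(x, m):
    """kappa * binom(x, m): e.g. 0.1 * 4*3/2 = 0.6 for a dimerization at
    x = 4, and 3*2*1/6 = 1 for the trimolecular channel at x = 3."""
    net = ReactionNetwork(["X"])
    net.add_reaction("r", {"X": m}, {"X": m + 1} if m else {"X": 1}, 1.0)
    lam = evaluate_propensities(net, [x])
    assert lam[0] == pytest.approx(falling_factorial_oracle(x, m))


def test_propensity_examples(birth_death, dimerization):
    assert evaluate_propensities(birth_death, [0]).tolist() == [2.0, 0.0]
    lam = evaluate_propensities(dimerization, [4, 0])
    assert lam[2] == pytest.approx(0.6)  # 0.1 * 4*3/2
    sch = build_fixture("schlogl_40", {"c1": 0, "c2": 1.0, "c3": 0, "c4": 0})
    assert evaluate_propensities(sch, [3])[1] == pytest.approx(1.0)  # 3*2*1/6


def test_drift_vector_examples(birth_death, dimerization):
    assert drift_vector(birth_death, [5]) == pytest.approx([-3.0])
    assert drift_vector(ReactionNetwork(["X"]), [7]).tolist() == [0.0]
    assert drift_vector(dimerization, [4, 0]) == pytest.approx([4.8, 0.6])


def test_unimolecular_affine_birth_death_and_chain(birth_death, chain):
    aff = unimolecular_affine(birth_death)
    assert aff.A.tolist() == [[-1.0]] and aff.b.tolist() == [2.0]
    aff = unimolecular_affine(chain)
    assert aff.A.tolist() == [[-2.0, 0.0], [2.0, -3.0]]
    assert aff.b.tolist() == [6.0, 0.0]


def test_unimolecular_affine_rejects_bimolecular(dimerization):
    with pytest.raises(ValueError):
        unimolecular_affine(dimerization)


def test_quadratic_drift_dimerization(dimerization):
    Q, lin, const = quadratic_drift(dimerization, [1.0, 2.0])
    assert np.allclose(Q, 0)            # conservation kills the quadratic
    assert lin == pytest.approx([-1.0, -2.0])
    assert const == pytest.approx(10.0)
    Q, lin, const = quadratic_drift(dimerization, [1.0, 1.0])
    assert Q[0, 0] == pytest.approx(-0.05)  # -kappa3/2 * (2 v1 - v2)
    assert np.allclose(Q, Q.T)


def test_quadratic_drift_zero_for_unimolecular(birth_death):
    Q, _, _ = quadratic_drift(birth_death, [3.0])
    assert np.all(Q == 0)


def test_decomposition_exactness_random_networks(rng):
    """x^T Q(v) x + lin @ x + const reproduces <v, drift(x)> exactly
    (stochastic falling-factorial convention) on random order-<=2
    networks and random lattice states."""
    worst = 0.0
    for _ in range(200):
        d = int(rng.integers(1, 6))
        net = random_mass_action_network(rng, d=d,
                                         n_reactions=int(rng.integers(1, 8)))
        v = rng.uniform(0.2, 3.0, d)
        Q, lin, const = quadratic_drift(net, v)
        for _ in range(50):
            x = rng.integers(0, 30, d).astype(float)
            lhs = float(v @ drift_vector(net, x))
            rhs = float(x @ Q @ x + lin @ x + const)
            denom = max(1.0, abs(lhs))
            worst = max(worst, abs(lhs - rhs) / denom)
    assert worst <= 1e-12


def test_metzler_property_random_unimolecular(rng):
    for _ in range(50):
        net = random_mass_action_network(rng, d=int(rng.integers(1, 5)),
                                         n_reactions=5, max_order=1)
        A = unimolecular_affine(net).A
        off = A - np.diag(np.diag(A))
        assert np.min(off) >= 0


def test_diffusivity(birth_death, dimerization):
    assert diffusivity(birth_death, [1.0], [3]) == pytest.approx(5.0)
    # conserved channel contributes nothing
    full = diffusivity(dimerization, [1.0, 2.0], [10, 3])
    no_dim = build_fixture("dimerization_29", {"k3": 0.0})
    assert full == pytest.approx(diffusivity(no_dim, [1.0, 2.0], [10, 3]))
    with pytest.raises(ValueError):
        diffusivity(birth_death, [0.0], [3])


def test_conservation_vector(dimerization, sir):
    v = conservation_vector(dimerization)
    assert v[1] == pytest.approx(2 * v[0])
    Sb = dimerization.bimolecular_stoichiometry()
    assert np.max(np.abs(Sb.T @ v)) <= 1e-9
    v = conservation_vector(sir)
    assert v[0] == pytest.approx(v[1])  # v_S = v_I
    # full-row-rank S_b: annihilation X1 + X2 -> 0 alone
    up = build_fixture("unstable_pair_26")
    assert conservation_vector(up) is None


def test_verify_dd_examples(birth_death, dimerization):
    cert = verify_dd(birth_death, [1.0])
    assert (cert.c1, cert.c2, cert.gamma) == (1.0, 2.0, 2.0)
    # minimal c3: max over x of (2 + x) / (1 + x) = 2 at x = 0
    assert cert.c3 == pytest.approx(2.0)
    assert cert.dd1_verified and cert.dd2_verified

    cert = verify_dd(dimerization, [1.0, 2.0])
    assert cert.c1 == pytest.approx(1.0)
    assert cert.c2 == pytest.approx(10.0)
    assert cert.gamma == pytest.approx(10.0)
    with pytest.raises(ValueError):
        verify_dd(birth_death, [-1.0])


def test_verify_dd_scalar_oracle(birth_death):
    """c2 - c1 <v,x> - <v,drift(x)> >= 0 on the whole lattice ray, and the
    claimed constants are tight (slack 0 somewhere)."""
    cert = verify_dd(birth_death, [1.0])
    xs = np.arange(0, 10001.0)
    drift = 2.0 - xs
    slack = cert.c2 - cert.c1 * xs - drift
    assert np.min(slack) >= -1e-12
    assert np.min(slack) <= 1e-12  # tight
    diff = 2.0 + xs
    assert np.min(cert.c3 * (1 + xs) - diff) >= -1e-12


def test_no_dd1_for_unstable_pair_on_grid():
    """No positive-weight certificate exists at grid resolution for the
    diverging pair-annihilation network."""
    net = build_fixture("unstable_pair_26")
    for a in np.logspace(-2, 2, 20):
        for b in np.logspace(-2, 2, 20):
            cert = verify_dd(net, [a, b])
            assert not cert.dd1_verified


def test_certificate_audit_soundness(birth_death, dimerization):
    for net, v in [(birth_death, [1.0]), (dimerization, [1.0, 2.0])]:
        cert = verify_dd(net, v)
        aud = audit_certificate(net, cert, n_states=2000, max_count=1000, seed=3)
        assert aud["dd1_worst_slack"] >= -1e-9
        assert aud["dd2_worst_slack"] >= -1e-9
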