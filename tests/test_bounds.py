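"""Optimal attractors, moment tables, light tails, closure audit."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from ergokit import (
    build_fixture,
    moment_bounds,
    optimal_attractor_conserved,
    optimal_attractor_qneg,
    optimal_attractor_unimolecular,
    verify_dd,
)
from ergokit.bounds import closure_audit, distance_to_attractor, light_tail_flags
from ergokit.drift import unimolecular_affine
from ergokit.ergodicity import certificate_lp
from ergokit.fixtures import random_mass_action_network
from ergokit.network import ReactionNetwork


def truncated_cme_stationary_mean(net, n_max):
    """Stationary mean of a small network by direct CME truncation
    (independent oracle; brute state enumeration + generator null space)."""
    import itertools

    from ergokit.drift import evaluate_propensities

    states = [np.array(s) for s in itertools.product(range(n_max + 1),
                                                     repeat=net.d)]
    index = {tuple(s): i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    Z = net.stoichiometry_matrix().T
    for i, x in enumerate(states):
        lam = evaluate_propensities(net, x)
        for k in range(net.K):
            y = x + Z[k]
            if np.any(y < 0) or np.any(y > n_max):
                continue  # reflecting truncation
            j = index[tuple(y)]
            Q[j, i] += lam[k]
            Q[i, i] -= lam[k]
    w, vec = np.linalg.eig(Q)
    pi = np.real(vec[:, np.argmin(np.abs(w))])
    pi = np.abs(pi) / np.abs(pi).sum()
    return sum(p * np.asarray(s, float) for p, s in zip(pi, states))


def test_birth_death_tightness(birth_death):
    """gamma* equals the Poisson stationary mean k/gd exactly."""
    att = optimal_attractor_unimolecular(birth_death)
    assert abs(att.gamma_star - 2.0) / 2.0 <= 1e-9
    assert att.v_star[0] == pytest.approx(1.0)


def test_chain_attractor_analytic(chain):
    """0 ->(6) S1 ->(2) S2 ->(3) 0: the optimum of min c2(v)/c1 subject
    to A^T v <= -c1 v, v >= 1 is gamma* = 12 at c1 = 1, v = (2, 1)
    (analytically F(c1) = 12 / (c1 (2 - c1))), and it upper-bounds the
    truncated-CME stationary mean of <v*, X>."""
    att = optimal_attractor_unimolecular(chain)
    assert att.gamma_star == pytest.approx(12.0, rel=1e-6)
    assert att.c1_star == pytest.approx(1.0, rel=1e-5)
    mean = truncated_cme_stationary_mean(chain, 14)
    assert float(att.v_star @ mean) <= att.gamma_star + 1e-6


def test_attractor_certificate_invariant(chain):
    att = optimal_attractor_unimolecular(chain)
    A = unimolecular_affine(chain).A
    assert np.all(A.T @ att.v_star <= -att.c1_star * att.v_star + 1e-9)


def test_dimerization_conserved_attractor(dimerization):
    att = optimal_attractor_conserved(dimerization)
    assert att.gamma_star == pytest.approx(10.0, rel=1e-9)
    assert att.v_star[1] == pytest.approx(2 * att.v_star[0])


def test_sir_attractor_closed_form(sir):
    # birth rate / min death rate under v = (1,1,1)
    att = optimal_attractor_conserved(sir)
    assert att.gamma_star == pytest.approx(10.0, rel=1e-9)


def test_qneg_reduces_to_unimolecular(birth_death):
    a1 = optimal_attractor_unimolecular(birth_death)
    a2 = optimal_attractor_qneg(birth_death)
    assert a2.gamma_star == pytest.approx(a1.gamma_star, rel=1e-6)


def test_qneg_vs_conserved_dimerization(dimerization):
    g_cons = optimal_attractor_conserved(dimerization).gamma_star
    g_qneg = optimal_attractor_qneg(dimerization).gamma_star
    assert g_qneg >= g_cons - 1e-6  # different feasible sets; qneg never smaller here


def test_qneg_not_certifiable_for_autocatalysis():
    net = ReactionNetwork(["X", "Y"])
    net.add_reaction("auto", {"X": 1, "Y": 1}, {"X": 2, "Y": 2}, 1.0)
    net.add_reaction("d1", {"X": 1}, {}, 1.0)
    net.add_reaction("d2", {"Y": 1}, {}, 1.0)
    with pytest.raises(ValueError):
        optimal_attractor_qneg(net)


def test_bisection_matches_grid_bruteforce(rng):
    """Outer-search optimum agrees with a brute 2-D scan over (c1, v
    directions) on random stable unimolecular networks."""
    for _ in range(20):
        d = int(rng.integers(1, 4))
        net = random_mass_action_network(rng, d=d, n_reactions=4,
                                         max_order=1, stable=True)
        att = optimal_attractor_unimolecular(net)
        A = unimolecular_affine(net).A
        c1_hi = -np.max(np.linalg.eigvals(A).real)
        best = math.inf
        for c1 in np.linspace(c1_hi / 200, c1_hi, 200):
            sol = certificate_lp(net, c1)
            if sol is None:
                continue
            v, c2 = sol
            # evaluate at the decay rate the LP solution actually attains
            c1_eff = float(np.min(-(A.T @ v) / v))
            if c1_eff > 0:
                best = min(best, c2 / c1_eff)
        assert att.gamma_star <= best * (1 + 1e-6)
        assert att.gamma_star >= best * (1 - 0.01) - 1e-9


def test_moment_table_birth_death(birth_death):
    cert = verify_dd(birth_death, [1.0])
    tab = moment_bounds(cert, 3, [0])
    assert tab.asymptotic(1) == pytest.approx(2.0)   # = gamma; Poisson mean 2
    assert tab.uniform(1) >= tab.asymptotic(1)
    # Poisson(2): E[X^2] = 6, E[X^3] = 26 -- bounds must dominate
    assert tab.asymptotic(2) >= 6.0
    assert tab.asymptotic(3) >= 26.0


def test_moment_table_monotone_in_c1(birth_death):
    cert = verify_dd(birth_death, [1.0])
    weaker = type(cert)(v=cert.v, c1=cert.c1 / 2, c2=cert.c2, c3=cert.c3,
                        gamma=2 * cert.gamma, zeta_bar=cert.zeta_bar,
                        dd1_verified=True, dd2_verified=True)
    t_strong = moment_bounds(cert, 4, [0])
    t_weak = moment_bounds(weaker, 4, [0])
    for n in range(1, 5):
        assert t_strong.asymptotic(n) <= t_weak.asymptotic(n) + 1e-12
        assert t_strong.uniform(n) <= t_weak.uniform(n) + 1e-12


def test_moment_table_restricted_without_dd2():
    sch = build_fixture("schlogl_40")
    from ergokit import scalar_polynomial_drift

    cert = scalar_polynomial_drift(sch)
    tab = moment_bounds(cert, 5, [250])
    assert list(tab.orders) == [1]
    assert "n = 1" in tab.validity_condition


def test_light_tail_flags(birth_death, dimerization):
    assert light_tail_flags(verify_dd(birth_death, [1.0]))["uniform_light_tailed"]
    assert light_tail_flags(verify_dd(dimerization, [1.0, 2.0]))["stationary_light_tailed"]
    from ergokit import scalar_polynomial_drift

    flags = light_tail_flags(scalar_polynomial_drift(build_fixture("schlogl_40")))
    assert not flags["uniform_light_tailed"]
    assert "DD2" in flags["reason"]


def test_closure_audit_on_boundary(dimerization):
    """The variance-neglect closure of the dimerization network settles
    exactly on the attractor boundary: <v, y*> = gamma*."""
    att = optimal_attractor_conserved(dimerization)
    aud = closure_audit(dimerization, att)
    assert aud.jacobian_stable
    vdot = float(att.v_star @ aud.closed_equilibrium)
    assert vdot == pytest.approx(att.gamma_star, rel=1e-6)
    assert aud.error_lower_bound <= 1e-6
    assert aud.inside_attractor


def test_closure_audit_inflated_and_shrunk(dimerization):
    from ergokit.bounds import AttractorResult

    att = optimal_attractor_conserved(dimerization)
    fat = AttractorResult(v_star=att.v_star, c1_star=att.c1_star,
                          c2_star=att.c2_star * 10, gamma_star=att.gamma_star * 10)
    aud = closure_audit(dimerization, fat)
    assert aud.inside_attractor and aud.error_lower_bound == 0.0

    # shrink gamma just enough that the half-space projection stays in
    # the nonnegative orthant: distance = (⟨v, y⟩ - gamma) / |v|
    thin = AttractorResult(v_star=att.v_star, c1_star=att.c1_star,
                           c2_star=att.c2_star * 0.8, gamma_star=att.gamma_star * 0.8)
    aud = closure_audit(dimerization, thin)
    assert not aud.inside_attractor
    y = aud.closed_equilibrium
    expected = max(0.0, float(att.v_star @ y) - thin.gamma_star) / np.linalg.norm(att.v_star)
    assert aud.error_lower_bound == pytest.approx(expected, rel=1e-6)


def test_distance_formula_vs_generic_projection(rng):
    """KKT projection agrees with a generic constrained minimizer on
    random points, including ones needing the nonnegativity face."""
    for _ in range(100):
        d = int(rng.integers(1, 5))
        v = rng.uniform(0.2, 3.0, d)
        gamma = float(rng.uniform(0.5, 5.0))
        y = rng.uniform(-2.0, 6.0, d)
        dist = distance_to_attractor(v, gamma, y)
        res = minimize(lambda x: np.sum((x - y) ** 2), np.maximum(y, 0.0),
                       constraints=[{"type": "ineq", "fun": lambda x: gamma - v @ x}],
                       bounds=[(0, None)] * d, method="SLSQP",
                       options={"ftol": 1e-14, "maxiter": 500})
        assert dist == pytest.approx(math.sqrt(max(res.fun, 0.0)), abs=1e-4)


def test_unstable_network_not_certifiable():
    net = build_fixture("well_jumping_22")
    with pytest.raises(ValueError):
        optimal_attractor_qneg(net)
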