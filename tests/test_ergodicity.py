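"""Certificate searches: Metzler LP, robust families, quadratic programs,
copositivity, Lotka-Volterra, scalar polynomial route, dispatcher."""

import math

import numpy as np
import pytest

from ergokit import (
    analyze,
    analyze_bimolecular_conserved,
    analyze_bimolecular_general,
    analyze_lotka_volterra,
    analyze_robust,
    analyze_unimolecular,
    build_fixture,
    copositivity_test,
    hurwitz_test,
    positive_linear_certificate,
    scalar_polynomial_drift,
    verify_dd,
)
from ergokit.drift import audit_certificate
from ergokit.ergodicity import (
    detect_bounded_species,
    reduce_bounded_species,
)
from ergokit.fixtures import FIXTURES
from ergokit.network import ReactionNetwork


def random_metzler(rng, d):
    A = rng.uniform(0.0, 1.0, (d, d))
    np.fill_diagonal(A, rng.uniform(-4.0, 0.5, d))
    return A


# ---------------------------------------------------------------------------
# Hurwitz / positive certificate
# ---------------------------------------------------------------------------

def test_hurwitz_examples():
    assert hurwitz_test([[-1.0]])
    assert not hurwitz_test([[0.0, 1.0], [-1.0, 0.0]])  # imaginary spectrum
    assert hurwitz_test([[-1.0, 0.0], [1.0, -2.0]])     # triangular


def test_positive_certificate_examples():
    v = positive_linear_certificate(np.array([[-1.0]]))
    assert v is not None and v[0] >= 1
    A = np.array([[-1.0, 0.0], [1.0, -1.0]])
    v = positive_linear_certificate(A)
    assert v is not None
    assert np.all(A.T @ v < 0) and v[0] > v[1] >= 1
    assert positive_linear_certificate(np.array([[1.0]])) is None
    with pytest.raises(ValueError):
        positive_linear_certificate(np.array([[-1.0, -0.5], [0.0, -1.0]]))


def test_lp_hurwitz_equivalence_500_random_metzler(rng):
    """Feasibility of the positive-vector LP coincides with spectral
    stability on 500 random Metzler matrices up to d = 8 (matrices
    within the strictness margin of the imaginary axis are excluded)."""
    checked = discordant = 0
    while checked < 500:
        d = int(rng.integers(1, 9))
        A = random_metzler(rng, d)
        if abs(np.max(np.linalg.eigvals(A).real)) < 1e-4:
            continue
        checked += 1
        if hurwitz_test(A) != (positive_linear_certificate(A) is not None):
            discordant += 1
    assert discordant == 0


# ---------------------------------------------------------------------------
# unimolecular / robust
# ---------------------------------------------------------------------------

def test_analyze_unimolecular_birth_death(birth_death):
    rep = analyze_unimolecular(birth_death)
    assert rep.verdict == "ergodic"
    assert rep.moment_conclusion == "all_orders"
    assert rep.light_tailed


def test_analyze_unimolecular_supercritical_autocatalysis():
    net = ReactionNetwork(["X"])
    net.add_reaction("b", {}, {"X": 1}, 1.0)
    net.add_reaction("auto", {"X": 1}, {"X": 2}, 2.0)
    net.add_reaction("d", {"X": 1}, {}, 1.0)
    assert analyze_unimolecular(net).verdict == "no_certificate_found"


def test_robust_birth_death(birth_death):
    birth_death.rate_intervals["death"] = (0.5, 2.0)
    rep = analyze_robust(birth_death)
    assert rep.verdict == "ergodic_robust"


def test_robust_conversion_chain(chain):
    chain.rate_intervals["c"] = (1.0, 2.0)
    chain.rate_intervals["d"] = (1.0, 2.0)
    rep = analyze_robust(chain)
    assert rep.verdict == "ergodic_robust"


def test_robust_autocatalysis_straddling():
    net = ReactionNetwork(["X"])
    net.add_reaction("b", {}, {"X": 1}, 1.0)
    net.add_reaction("auto", {"X": 1}, {"X": 2}, 1.0)
    net.add_reaction("d", {"X": 1}, {}, 1.2)
    net.rate_intervals["auto"] = (0.5, 1.5)   # straddles the death rate
    rep = analyze_robust(net)
    assert rep.verdict in ("no_certificate_found", "bound_matrix_unavailable")


def test_robust_implies_pointwise(rng, chain):
    """Every member of a robustly certified interval family is
    individually certifiable."""
    chain.rate_intervals["c"] = (1.0, 2.0)
    chain.rate_intervals["d"] = (1.5, 2.5)
    assert analyze_robust(chain).verdict == "ergodic_robust"
    for _ in range(50):
        c = float(rng.uniform(1.0, 2.0))
        dd = float(rng.uniform(1.5, 2.5))
        net = ReactionNetwork(["S1", "S2"])
        net.add_reaction("b", {}, {"S1": 1}, 6.0)
        net.add_reaction("c", {"S1": 1}, {"S2": 1}, c)
        net.add_reaction("d", {"S2": 1}, {}, dd)
        assert analyze_unimolecular(net).verdict == "ergodic"


# ---------------------------------------------------------------------------
# bimolecular programs
# ---------------------------------------------------------------------------

def test_conserved_program_dimerization(dimerization):
    rep = analyze_bimolecular_conserved(dimerization)
    assert rep.verdict == "ergodic"
    v = rep.certificate.v
    assert v[1] == pytest.approx(2 * v[0])
    assert rep.moment_conclusion == "all_orders"


def test_conserved_program_prerequisite():
    up = build_fixture("unstable_pair_26")
    rep = analyze_bimolecular_conserved(up)
    assert rep.verdict == "prerequisite_failed"


def test_componentwise_program(dimerization):
    rep = analyze_bimolecular_general(dimerization, "componentwise_lp")
    assert rep.verdict == "ergodic"
    # feasibility needs 2 v1 >= v2 so the lone Q entry stays nonpositive
    v = rep.certificate.v
    assert 2 * v[0] >= v[1] - 1e-9


def test_negdef_program_infeasible_for_autocatalytic_pair():
    net = ReactionNetwork(["X", "Y"])
    net.add_reaction("b1", {}, {"X": 1}, 1.0)
    net.add_reaction("b2", {}, {"Y": 1}, 1.0)
    net.add_reaction("auto", {"X": 1, "Y": 1}, {"X": 2, "Y": 2}, 1.0)
    net.add_reaction("d1", {"X": 1}, {}, 1.0)
    net.add_reaction("d2", {"Y": 1}, {}, 1.0)
    for mode in ("componentwise_lp", "negdef_sdp"):
        assert analyze_bimolecular_general(net, mode).verdict == "no_certificate_found"


# ---------------------------------------------------------------------------
# copositivity
# ---------------------------------------------------------------------------

def test_copositivity_examples():
    assert copositivity_test(np.eye(4))["copositive"]
    res = copositivity_test(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    assert not res["copositive"]
    x = res["witness"]
    assert np.all(x >= 0) and x @ np.array([[0.0, -1.0], [-1.0, 0.0]]) @ x < 0
    assert copositivity_test(np.array([[1.0, -1.0], [-1.0, 1.0]]))["copositive"]


def test_copositivity_witness_soundness(rng):
    M0 = np.array([[0.0, -1.0], [-1.0, 0.0]])
    for _ in range(100):
        d = int(rng.integers(2, 6))
        M = rng.uniform(-1, 1, (d, d))
        M = (M + M.T) / 2
        res = copositivity_test(M)
        if not res["copositive"]:
            x = res["witness"]
            assert np.all(x >= -1e-12)
            assert x @ M @ x < 0
        else:
            # spot check on simplex samples
            for _ in range(200):
                x = rng.dirichlet(np.ones(d))
                assert x @ M @ x >= -1e-8


def test_copositive_but_not_psd():
    # entrywise nonnegative matrices are copositive even when indefinite
    M = np.array([[0.0, 2.0], [2.0, 0.0]])
    assert np.min(np.linalg.eigvalsh(M)) < 0
    assert copositivity_test(M)["copositive"]


# ---------------------------------------------------------------------------
# Lotka-Volterra and scalar routes
# ---------------------------------------------------------------------------

def test_lv_logistic_single_species():
    lv = build_fixture("lotka_volterra_39",
                       {"a": (1.0,), "b": (2.0,), "d": (1.0,), "c": ((0.05,),)})
    rep = analyze_lotka_volterra(lv)
    assert rep.verdict == "ergodic"


def test_lv_diagonally_dominant_competition():
    lv = build_fixture("lotka_volterra_39")
    rep = analyze_lotka_volterra(lv)
    assert rep.verdict == "ergodic"
    assert rep.method.startswith("lv_")


def test_lv_without_competition_fails():
    lv = build_fixture("lotka_volterra_39", {"c": ((0.0, 0.0), (0.0, 0.0))})
    rep = analyze_lotka_volterra(lv)
    assert rep.verdict == "no_certificate_found"


def test_lv_template_mismatch():
    with pytest.raises(ValueError):
        analyze_lotka_volterra(build_fixture("dimerization_29"))


def test_scalar_route_schlogl():
    sch = build_fixture("schlogl_40")
    cert = scalar_polynomial_drift(sch)
    assert cert.dd1_verified
    assert not cert.dd2_verified          # cubic diffusivity
    assert math.isinf(cert.c3)
    # DD1 checked on the lattice directly
    from ergokit.drift import drift_vector

    xs = np.arange(0, 3000)
    drifts = np.array([drift_vector(sch, [x])[0] for x in xs])
    assert np.all(drifts <= cert.c2 - cert.c1 * xs + 1e-9)


def test_scalar_route_pure_birth_none():
    net = ReactionNetwork(["X"])
    net.add_reaction("b", {}, {"X": 1}, 1.0)
    net.add_reaction("auto3", {"X": 3}, {"X": 4}, 0.5)
    cert = scalar_polynomial_drift(net)
    assert not cert.dd1_verified


def test_scalar_route_birth_death_exact(birth_death):
    cert = scalar_polynomial_drift(birth_death, c1=1.0)
    assert cert.c2 == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# bounded-species reduction and dispatcher
# ---------------------------------------------------------------------------

def test_gene_states_detected_and_reduced():
    circ = build_fixture("circadian_vilar")
    x0 = np.zeros(9, dtype=int)
    x0[circ.species_index("DA")] = 1
    x0[circ.species_index("DR")] = 1
    caps = detect_bounded_species(circ, x0)
    assert {"DA", "DA_b", "DR", "DR_b"} <= set(caps)
    assert all(caps[s] == pytest.approx(1.0) for s in ("DA", "DA_b"))
    red = reduce_bounded_species(circ, caps)
    assert set(red.species) == {"MA", "MR", "A", "R", "C"}


def test_conversion_network_is_finite_state(conversion):
    rep = analyze(conversion, x0=np.array([3, 0]))
    assert rep.verdict == "ergodic"
    assert rep.method == "finite_state_space"


@pytest.mark.parametrize("name, expected", [
    ("birth_death", "ergodic"),
    ("dimerization_29", "ergodic"),
    ("feedback_loop_34", "ergodic"),
    ("toggle_switch_35", "ergodic"),
    ("repressilator_36", "ergodic"),
    ("sir_37", "ergodic"),
    ("circadian_vilar", "ergodic"),
    ("p53_38", "ergodic"),
    ("lotka_volterra_39", "ergodic"),
    ("schlogl_40", "ergodic"),
    ("well_jumping_22", "no_certificate_found"),
    ("unstable_pair_26", "no_certificate_found"),
    ("carcinogenesis_41", "no_certificate_found"),
])
def test_dispatcher_fixture_verdicts(name, expected):
    rep = analyze(build_fixture(name))
    assert rep.verdict == expected, rep.attempts
    if expected == "no_certificate_found":
        # the ladder never claims non-ergodicity
        assert rep.certificate is None or not rep.certificate.dd1_verified


def test_every_issued_certificate_reverifies():
    for name in ("birth_death", "dimerization_29", "sir_37", "circadian_vilar",
                 "lotka_volterra_39"):
        net = build_fixture(name)
        rep = analyze(net)
        assert rep.verdict == "ergodic"
        work = net
        if rep.reduced_species:
            work = reduce_bounded_species(net, rep.bounded_species)
        cert = rep.certificate
        assert verify_dd(work, cert.v, c1_request=cert.c1).dd1_verified \
            or cert.notes.startswith("scalar")
        aud = audit_certificate(work, cert, n_states=500, max_count=1000, seed=9)
        assert aud["dd1_worst_slack"] >= -1e-9


def test_degradation_monotonicity(dimerization):
    """Adding a degradation channel never destroys a certificate: the
    same weight vector re-verifies."""
    cert = verify_dd(dimerization, [1.0, 2.0])
    assert cert.dd1_verified
    dimerization.add_reaction("extra_deg", {"X1": 1}, {}, 0.7)
    cert2 = verify_dd(dimerization, [1.0, 2.0])
    assert cert2.dd1_verified
    assert cert2.c1 >= cert.c1 - 1e-12


def test_structural_sweep_small():
    """Log-uniform random rates stay certifiable (spot check; the full
    100-draw sweeps run in the acceptance suite)."""
    rng = np.random.default_rng(5)
    for name in ("toggle_switch_35", "sir_37"):
        defaults = FIXTURES[name]().params
        for _ in range(10):
            params = {k: float(10 ** rng.uniform(-2, 2)) for k in defaults}
            assert analyze(build_fixture(name, params)).verdict == "ergodic"
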