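"""Example networks bundled as constructible fixtures.

Each fixture is a builder ``(params) -> ReactionNetwork`` with documented
species ordering and default rate values.  Defaults for the qualitative
fixtures (``well_jumping_22``, ``unstable_pair_26``, ``carcinogenesis_41``)
were chosen to realize the regimes the models are meant to illustrate
(bistable well with a reachable escape region; globally stable rate
equations with stochastically diverging moments; supercritical mutant
growth) -- see ``docs/methods.md`` for the tuning rules.

Registry
--------
birth_death        X born at constant rate, degraded first-order (didactic).
well_jumping_22    single species with autocatalytic second-order birth:
                   bistable drift whose upper region explodes.
unstable_pair_26   birth + pair-annihilation: the reaction rate equations
                   are globally exponentially stable (per conservation
                   leaf) but the stochastic moments grow without bound.
dimerization_29    birth/death of a monomer that dimerizes; the canonical
                   conserved bimolecular example.
feedback_loop_34   mRNA/protein/dimer loop, transcription under an
                   arbitrary bounded feedback function.
toggle_switch_35   two mutually repressing genes, bounded repression.
repressilator_36   n-gene ring oscillator (default n = 3), bounded repression.
sir_37             open SIR epidemic with demography and waning immunity.
circadian_vilar    the Vilar activator-repressor clock: 9 species,
                   18 reactions, mass-action.
p53_38             p53/Mdm2 oscillator with saturating feedback degradation.
lotka_volterra_39  open competitive Lotka-Volterra community (default 2 spp).
schlogl_40         Schloegl's trimolecular bistable switch.
carcinogenesis_41  healthy/mutant cell population with supercritical mutants.
"""

from __future__ import annotations

import numpy as np

from .network import ReactionNetwork

__all__ = ["FIXTURES", "build_fixture", "fixture_names", "default_initial_state"]


def _with_defaults(params, defaults, name):
    p = dict(defaults)
    unknown = set(params or {}) - set(defaults)
    if unknown:
        raise KeyError(f"fixture {name!r}: unknown parameters {sorted(unknown)}")
    p.update(params or {})
    return p


def birth_death(params=None) -> ReactionNetwork:
    """``0 -> X`` at rate k, ``X -> 0`` at rate gd.  Stationary law Poisson(k/gd)."""
    p = _with_defaults(params, {"k": 2.0, "gd": 1.0}, "birth_death")
    net = ReactionNetwork(["X"], params=p, name="birth_death")
    net.add_reaction("birth", {}, {"X": 1}, p["k"], rate_symbol="k")
    net.add_reaction("death", {"X": 1}, {}, p["gd"], rate_symbol="gd")
    return net


def well_jumping_22(params=None) -> ReactionNetwork:
    """``0 -> X``, ``X -> 0``, ``2X -> 3X``.

    The deterministic drift ``k1 - k2*x + (k3/2)*x^2`` has two positive
    roots; the smaller fixed point is locally stable, the larger unstable.
    Defaults (k1=4, k2=1, k3=0.12) put the stochastic drift roots near
    x = 5.5 and x = 12.2 (deterministic: 6.7 and 10), so the escape
    region is well inside the reachable range and guarded SSA runs
    terminate quickly.
    """
    p = _with_defaults(params, {"k1": 4.0, "k2": 1.0, "k3": 0.12}, "well_jumping_22")
    net = ReactionNetwork(["X"], params=p, name="well_jumping_22")
    net.add_reaction("birth", {}, {"X": 1}, p["k1"], rate_symbol="k1")
    net.add_reaction("death", {"X": 1}, {}, p["k2"], rate_symbol="k2")
    net.add_reaction("auto", {"X": 2}, {"X": 3}, p["k3"], rate_symbol="k3")
    return net


def unstable_pair_26(params=None) -> ReactionNetwork:
    """Birth + pair-annihilation: ``0 -> X1`` (k1), ``0 -> X2`` (k2),
    ``X1 + X2 -> 0`` (k3), with k1 = k2.

    Deterministically the difference ``x1 - x2`` is conserved; on every
    leaf ``x1 - x2 = c`` the rate equations have a unique globally
    exponentially stable equilibrium (the Jacobian has one strictly
    negative eigenvalue plus the zero mode of the conservation).
    Stochastically the difference performs an *unbiased random walk*
    (birth of X1 at rate k1, of X2 at rate k2, annihilation leaves it
    unchanged), so ``|X1 - X2|`` -- and with it every moment of the
    counts -- grows without bound and no stationary distribution exists.
    """
    p = _with_defaults(params, {"k1": 1.0, "k2": 1.0, "k3": 1.0}, "unstable_pair_26")
    net = ReactionNetwork(["X1", "X2"], params=p, name="unstable_pair_26")
    net.add_reaction("b1", {}, {"X1": 1}, p["k1"], rate_symbol="k1")
    net.add_reaction("b2", {}, {"X2": 1}, p["k2"], rate_symbol="k2")
    net.add_reaction("annih", {"X1": 1, "X2": 1}, {}, p["k3"], rate_symbol="k3")
    return net


def dimerization_29(params=None) -> ReactionNetwork:
    """``0 -> X1`` (k1), ``X1 -> 0`` (k2), ``2 X1 -> X2`` (k3), ``X2 -> 0`` (k4)."""
    p = _with_defaults(
        params, {"k1": 10.0, "k2": 1.0, "k3": 0.1, "k4": 1.0}, "dimerization_29"
    )
    net = ReactionNetwork(["X1", "X2"], params=p, name="dimerization_29")
    net.add_reaction("birth", {}, {"X1": 1}, p["k1"], rate_symbol="k1")
    net.add_reaction("deg1", {"X1": 1}, {}, p["k2"], rate_symbol="k2")
    net.add_reaction("dim", {"X1": 2}, {"X2": 1}, p["k3"], rate_symbol="k3")
    net.add_reaction("deg2", {"X2": 1}, {}, p["k4"], rate_symbol="k4")
    return net


def feedback_loop_34(params=None) -> ReactionNetwork:
    """mRNA M -> protein P -> dimer D, with D feeding back on transcription
    through an arbitrary bounded nonnegative function (Hill form as hint).

    Species order: M, P, D.
    """
    defaults = {"k0": 10.0, "gM": 1.0, "kp": 2.0, "gP": 1.0,
                "kd": 0.1, "ku": 1.0, "gD": 1.0}
    p = _with_defaults(params, defaults, "feedback_loop_34")
    net = ReactionNetwork(["M", "P", "D"], params=p, name="feedback_loop_34")
    net.add_reaction("tx", {}, {"M": 1}, kind="bounded_function", sup=p["k0"],
                     hint=f"{p['k0']}/(1+D)", rate_symbol="k0")
    net.add_reaction("deg_m", {"M": 1}, {}, p["gM"], rate_symbol="gM")
    net.add_reaction("tl", {"M": 1}, {"M": 1, "P": 1}, p["kp"], rate_symbol="kp")
    net.add_reaction("deg_p", {"P": 1}, {}, p["gP"], rate_symbol="gP")
    net.add_reaction("dim", {"P": 2}, {"D": 1}, p["kd"], rate_symbol="kd")
    net.add_reaction("undim", {"D": 1}, {"P": 2}, p["ku"], rate_symbol="ku")
    net.add_reaction("deg_d", {"D": 1}, {}, p["gD"], rate_symbol="gD")
    return net


def toggle_switch_35(params=None) -> ReactionNetwork:
    """Two genes repressing each other through bounded functions.

    Species order: M1, P1, M2, P2 (mRNA and protein of each gene).
    """
    defaults = {"k01": 5.0, "k02": 5.0, "gM1": 1.0, "gM2": 1.0,
                "kp1": 2.0, "kp2": 2.0, "gP1": 1.0, "gP2": 1.0}
    p = _with_defaults(params, defaults, "toggle_switch_35")
    net = ReactionNetwork(["M1", "P1", "M2", "P2"], params=p, name="toggle_switch_35")
    net.add_reaction("tx1", {}, {"M1": 1}, kind="bounded_function", sup=p["k01"],
                     hint=f"{p['k01']}/(1+P2**2)", rate_symbol="k01")
    net.add_reaction("deg_m1", {"M1": 1}, {}, p["gM1"], rate_symbol="gM1")
    net.add_reaction("tl1", {"M1": 1}, {"M1": 1, "P1": 1}, p["kp1"], rate_symbol="kp1")
    net.add_reaction("deg_p1", {"P1": 1}, {}, p["gP1"], rate_symbol="gP1")
    net.add_reaction("tx2", {}, {"M2": 1}, kind="bounded_function", sup=p["k02"],
                     hint=f"{p['k02']}/(1+P1**2)", rate_symbol="k02")
    net.add_reaction("deg_m2", {"M2": 1}, {}, p["gM2"], rate_symbol="gM2")
    net.add_reaction("tl2", {"M2": 1}, {"M2": 1, "P2": 1}, p["kp2"], rate_symbol="kp2")
    net.add_reaction("deg_p2", {"P2": 1}, {}, p["gP2"], rate_symbol="gP2")
    return net


def repressilator_36(params=None) -> ReactionNetwork:
    """n-gene ring repressilator with bounded repression functions.

    Species order: M1, P1, M2, P2, ..., Mn, Pn.  Gene i is repressed by
    protein i-1 (cyclically).  ``n`` is a structural parameter.
    """
    defaults = {"n": 3, "k0": 5.0, "gM": 1.0, "kp": 2.0, "gP": 1.0}
    p = _with_defaults(params, defaults, "repressilator_36")
    n = int(p["n"])
    if n < 2:
        raise ValueError("repressilator needs at least 2 genes")
    species = []
    for i in range(1, n + 1):
        species += [f"M{i}", f"P{i}"]
    net = ReactionNetwork(species, params=p, name="repressilator_36")
    for i in range(1, n + 1):
        rep = f"P{n if i == 1 else i - 1}"
        net.add_reaction(f"tx{i}", {}, {f"M{i}": 1}, kind="bounded_function",
                         sup=p["k0"], hint=f"{p['k0']}/(1+{rep}**2)")
        net.add_reaction(f"deg_m{i}", {f"M{i}": 1}, {}, p["gM"])
        net.add_reaction(f"tl{i}", {f"M{i}": 1}, {f"M{i}": 1, f"P{i}": 1}, p["kp"])
        net.add_reaction(f"deg_p{i}", {f"P{i}": 1}, {}, p["gP"])
    return net


def sir_37(params=None) -> ReactionNetwork:
    """Open SIR model with births, deaths, contamination and waning immunity.

    Species order: S, I, R.  Reactions: ``0 -> S`` (lam), ``S -> 0`` (dS),
    ``I -> 0`` (dI), ``R -> 0`` (dR), ``S + I -> 2I`` (beta),
    ``I -> R`` (gam), ``R -> S`` (rho).
    """
    defaults = {"lam": 10.0, "dS": 1.0, "dI": 1.0, "dR": 1.0,
                "beta": 0.1, "gam": 0.5, "rho": 0.2}
    p = _with_defaults(params, defaults, "sir_37")
    net = ReactionNetwork(["S", "I", "R"], params=p, name="sir_37")
    net.add_reaction("birth", {}, {"S": 1}, p["lam"], rate_symbol="lam")
    net.add_reaction("death_s", {"S": 1}, {}, p["dS"], rate_symbol="dS")
    net.add_reaction("death_i", {"I": 1}, {}, p["dI"], rate_symbol="dI")
    net.add_reaction("death_r", {"R": 1}, {}, p["dR"], rate_symbol="dR")
    net.add_reaction("contact", {"S": 1, "I": 1}, {"I": 2}, p["beta"], rate_symbol="beta")
    net.add_reaction("recover", {"I": 1}, {"R": 1}, p["gam"], rate_symbol="gam")
    net.add_reaction("wane", {"R": 1}, {"S": 1}, p["rho"], rate_symbol="rho")
    return net


def circadian_vilar(params=None) -> ReactionNetwork:
    """The Vilar activator-repressor circadian clock: 9 species, 18 reactions.

    Species order: DA, DA_b, DR, DR_b (free/bound activator and repressor
    genes), MA, MR (mRNAs), A, R (proteins), C (A:R complex).  All
    channels are mass-action.  Besides the 16 canonical channels, the
    bound activator also degrades on the gene (``DA_b -> DA``,
    ``DR_b -> DR`` at rate dA), which completes the 18-reaction listing;
    these channels are slow relative to unbinding (dA << thA, thR) and
    perturb the stationary averages by under 1%.
    """
    defaults = {"aA": 50.0, "aAb": 500.0, "aR": 0.01, "aRb": 50.0,
                "bA": 50.0, "bR": 5.0, "dMA": 10.0, "dMR": 0.5,
                "dA": 1.0, "dR": 0.2, "gA": 1.0, "gR": 1.0, "gC": 2.0,
                "thA": 50.0, "thR": 100.0}
    p = _with_defaults(params, defaults, "circadian_vilar")
    species = ["DA", "DA_b", "DR", "DR_b", "MA", "MR", "A", "R", "C"]
    net = ReactionNetwork(species, params=p, name="circadian_vilar")
    net.add_reaction("bindA", {"DA": 1, "A": 1}, {"DA_b": 1}, p["gA"], rate_symbol="gA")
    net.add_reaction("unbindA", {"DA_b": 1}, {"DA": 1, "A": 1}, p["thA"], rate_symbol="thA")
    net.add_reaction("bindR", {"DR": 1, "A": 1}, {"DR_b": 1}, p["gR"], rate_symbol="gR")
    net.add_reaction("unbindR", {"DR_b": 1}, {"DR": 1, "A": 1}, p["thR"], rate_symbol="thR")
    net.add_reaction("txA", {"DA": 1}, {"DA": 1, "MA": 1}, p["aA"], rate_symbol="aA")
    net.add_reaction("txA_b", {"DA_b": 1}, {"DA_b": 1, "MA": 1}, p["aAb"], rate_symbol="aAb")
    net.add_reaction("txR", {"DR": 1}, {"DR": 1, "MR": 1}, p["aR"], rate_symbol="aR")
    net.add_reaction("txR_b", {"DR_b": 1}, {"DR_b": 1, "MR": 1}, p["aRb"], rate_symbol="aRb")
    net.add_reaction("tlA", {"MA": 1}, {"MA": 1, "A": 1}, p["bA"], rate_symbol="bA")
    net.add_reaction("tlR", {"MR": 1}, {"MR": 1, "R": 1}, p["bR"], rate_symbol="bR")
    net.add_reaction("complex", {"A": 1, "R": 1}, {"C": 1}, p["gC"], rate_symbol="gC")
    net.add_reaction("release", {"C": 1}, {"R": 1}, p["dA"], rate_symbol="dA")
    net.add_reaction("deg_A", {"A": 1}, {}, p["dA"], rate_symbol="dA")
    net.add_reaction("deg_R", {"R": 1}, {}, p["dR"], rate_symbol="dR")
    net.add_reaction("deg_MA", {"MA": 1}, {}, p["dMA"], rate_symbol="dMA")
    net.add_reaction("deg_MR", {"MR": 1}, {}, p["dMR"], rate_symbol="dMR")
    net.add_reaction("deg_Ab", {"DA_b": 1}, {"DA": 1}, p["dA"], rate_symbol="dA")
    net.add_reaction("deg_Rb", {"DR_b": 1}, {"DR": 1}, p["dA"], rate_symbol="dA")
    return net


def p53_38(params=None) -> ReactionNetwork:
    """p53/Mdm2 oscillator with a saturating feedback degradation of p53.

    Species order: P (p53), M0 (Mdm2 precursor), M (Mdm2).  p53 is
    produced at a constant rate, degrades basally and is additionally
    degraded by Mdm2 through the saturating (hence per-Mdm2 bounded)
    propensity ``ak * M * P / (P + ks)``.
    """
    defaults = {"bx": 90.0, "ax": 0.2, "by": 1.1, "a0": 0.8, "ay": 0.8,
                "ak": 1.7, "ks": 1.0}
    p = _with_defaults(params, defaults, "p53_38")
    net = ReactionNetwork(["P", "M0", "M"], params=p, name="p53_38")
    net.add_reaction("prod_p", {}, {"P": 1}, p["bx"], rate_symbol="bx")
    net.add_reaction("deg_p", {"P": 1}, {}, p["ax"], rate_symbol="ax")
    net.add_reaction("fb_deg", {"P": 1}, {}, kind="scaled_bounded", sup=p["ak"],
                     per="M", hint=f"{p['ak']}*M*P/(P+{p['ks']})", rate_symbol="ak")
    net.add_reaction("prod_m0", {"P": 1}, {"P": 1, "M0": 1}, p["by"], rate_symbol="by")
    net.add_reaction("mature", {"M0": 1}, {"M": 1}, p["a0"], rate_symbol="a0")
    net.add_reaction("deg_m", {"M": 1}, {}, p["ay"], rate_symbol="ay")
    return net


def lotka_volterra_39(params=None) -> ReactionNetwork:
    """Open competitive Lotka-Volterra community (default two species).

    Per species i: immigration ``0 -> Si`` (a_i), reproduction
    ``Si -> 2 Si`` (b_i), death ``Si -> 0`` (d_i); competition
    ``Si + Sj -> Sj`` (c_ij, the competitor kills one individual of i)
    and intra-species crowding ``2 Si -> Si`` (c_ii).
    """
    defaults = {"a": (1.0, 1.0), "b": (2.0, 2.0), "d": (1.0, 1.0),
                "c": ((0.04, 0.01), (0.01, 0.04))}
    p = _with_defaults(params, defaults, "lotka_volterra_39")
    a, b, d = (np.atleast_1d(np.asarray(p[k], dtype=float)) for k in ("a", "b", "d"))
    c = np.atleast_2d(np.asarray(p["c"], dtype=float))
    n = len(a)
    species = [f"S{i+1}" for i in range(n)]
    scalar_params = {}
    for i in range(n):
        scalar_params[f"a{i+1}"] = float(a[i])
        scalar_params[f"b{i+1}"] = float(b[i])
        scalar_params[f"d{i+1}"] = float(d[i])
        for j in range(n):
            scalar_params[f"c{i+1}{j+1}"] = float(c[i, j])
    net = ReactionNetwork(species, params=scalar_params, name="lotka_volterra_39")
    for i, s in enumerate(species):
        net.add_reaction(f"imm_{s}", {}, {s: 1}, a[i], rate_symbol=f"a{i+1}")
        net.add_reaction(f"rep_{s}", {s: 1}, {s: 2}, b[i], rate_symbol=f"b{i+1}")
        net.add_reaction(f"death_{s}", {s: 1}, {}, d[i], rate_symbol=f"d{i+1}")
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            if c[i, j] <= 0:
                continue
            if i == j:
                net.add_reaction(f"crowd_{si}", {si: 2}, {si: 1}, c[i, i],
                                 rate_symbol=f"c{i+1}{i+1}")
            else:
                net.add_reaction(f"comp_{si}_{sj}", {si: 1, sj: 1}, {sj: 1},
                                 c[i, j], rate_symbol=f"c{i+1}{j+1}")
    return net


def schlogl_40(params=None) -> ReactionNetwork:
    """Schloegl's model: ``2X -> 3X`` (c1), ``3X -> 2X`` (c2), ``0 -> X`` (c3),
    ``X -> 0`` (c4).  Bistable for the default rates."""
    p = _with_defaults(
        params, {"c1": 0.18, "c2": 2.5e-4, "c3": 2200.0, "c4": 37.5}, "schlogl_40"
    )
    net = ReactionNetwork(["X"], params=p, name="schlogl_40")
    net.add_reaction("auto", {"X": 2}, {"X": 3}, p["c1"], rate_symbol="c1")
    net.add_reaction("back", {"X": 3}, {"X": 2}, p["c2"], rate_symbol="c2")
    net.add_reaction("birth", {}, {"X": 1}, p["c3"], rate_symbol="c3")
    net.add_reaction("death", {"X": 1}, {}, p["c4"], rate_symbol="c4")
    return net


def carcinogenesis_41(params=None) -> ReactionNetwork:
    """Healthy cells X (subcritical, with immigration) mutating into
    malignant cells Y; Y is a supercritical branching process under the
    defaults (b2 > d2), so counts grow without bound and the model is
    non-ergodic."""
    defaults = {"s": 1.0, "b1": 0.1, "d1": 0.3, "m": 0.05, "b2": 0.3, "d2": 0.2}
    p = _with_defaults(params, defaults, "carcinogenesis_41")
    net = ReactionNetwork(["X", "Y"], params=p, name="carcinogenesis_41")
    net.add_reaction("imm", {}, {"X": 1}, p["s"], rate_symbol="s")
    net.add_reaction("div", {"X": 1}, {"X": 2}, p["b1"], rate_symbol="b1")
    net.add_reaction("die", {"X": 1}, {}, p["d1"], rate_symbol="d1")
    net.add_reaction("mut", {"X": 1}, {"X": 1, "Y": 1}, p["m"], rate_symbol="m")
    net.add_reaction("div_y", {"Y": 1}, {"Y": 2}, p["b2"], rate_symbol="b2")
    net.add_reaction("die_y", {"Y": 1}, {}, p["d2"], rate_symbol="d2")
    return net


def random_mass_action_network(rng, d: int = 3, n_reactions: int = 6,
                               max_order: int = 2, stable: bool | None = None,
                               ) -> ReactionNetwork:
    """Random mass-action test instance.

    Draws reactant multisets of order <= ``max_order`` and small integer
    stoichiometric changes.  With ``stable=True`` every species gets a
    first-order degradation channel faster than its total production
    weight, yielding Hurwitz linear drift (useful for attractor
    cross-checks); ``stable=False`` adds an autocatalytic channel.
    """
    species = [f"S{i+1}" for i in range(d)]
    net = ReactionNetwork(species, name="random")
    for k in range(n_reactions):
        order = int(rng.integers(0, max_order + 1))
        reactants: dict[str, int] = {}
        for _ in range(order):
            s = species[int(rng.integers(0, d))]
            reactants[s] = reactants.get(s, 0) + 1
        products: dict[str, int] = {}
        for _ in range(int(rng.integers(0, 3))):
            s = species[int(rng.integers(0, d))]
            products[s] = products.get(s, 0) + 1
        zeta_zero = all(products.get(s, 0) == m for s, m in reactants.items()) and \
            all(s in reactants for s in products)
        if zeta_zero:
            s = species[int(rng.integers(0, d))]
            products[s] = products.get(s, 0) + 1
        net.add_reaction(f"r{k}", reactants, products,
                         float(rng.uniform(0.1, 3.0)))
    if stable is True:
        for i, s in enumerate(species):
            net.add_reaction(f"deg_{s}", {s: 1}, {}, float(rng.uniform(5.0, 10.0)))
    elif stable is False:
        s = species[0]
        net.add_reaction("auto", {s: 1}, {s: 2}, float(rng.uniform(5.0, 10.0)))
    return net


FIXTURES = {
    "birth_death": birth_death,
    "well_jumping_22": well_jumping_22,
    "unstable_pair_26": unstable_pair_26,
    "dimerization_29": dimerization_29,
    "feedback_loop_34": feedback_loop_34,
    "toggle_switch_35": toggle_switch_35,
    "repressilator_36": repressilator_36,
    "sir_37": sir_37,
    "circadian_vilar": circadian_vilar,
    "p53_38": p53_38,
    "lotka_volterra_39": lotka_volterra_39,
    "schlogl_40": schlogl_40,
    "carcinogenesis_41": carcinogenesis_41,
}

#: sensible starting states for simulation (zeros except where noted)
_X0 = {
    "circadian_vilar": {"DA": 1, "DR": 1},
    "well_jumping_22": {"X": 5},
    "unstable_pair_26": {"X1": 5, "X2": 5},
    "schlogl_40": {"X": 250},
    "carcinogenesis_41": {"X": 5},
    "lotka_volterra_39": {"S1": 5, "S2": 5},
}


def fixture_names() -> list[str]:
    return list(FIXTURES)


def build_fixture(name: str, params: dict | None = None) -> ReactionNetwork:
    """Construct a registered example network, overriding default rates."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        ) from None
    return builder(params)


def default_initial_state(net: ReactionNetwork) -> np.ndarray:
    """Default simulation start state for a fixture-built network."""
    x0 = np.zeros(net.d, dtype=np.int64)
    for name, count in _X0.get(net.name or "", {}).items():
        if name in net.species:
            x0[net.species_index(name)] = count
    return x0
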