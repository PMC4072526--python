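"""Optimal attractive compact sets and moment-bound tables.

The asymptotic first-order bound delivered by a DD certificate is
``gamma = c2 / c1``: the first-order moment of ``<v, X(t)>`` eventually
enters the half-space ``{x >= 0 : <v, x> <= gamma}``.  The *optimal*
attractor minimizes ``gamma`` over all certificates -- an outer scalar
search over ``c1`` whose inner problem (minimize ``c2(v)`` subject to
``v >= 1`` and decay at rate ``c1``) is a linear program with size
linear in the number of species.

Higher-order bounds follow from a comparison recursion obtained by
applying the generator to ``V^n = <v, x>^n``, expanding the jumps
binomially and absorbing every sub-leading power of ``V`` into
``1 + V^{n-1}``::

    K_n = n c2 + 2 c3 * sum_{j=2..n} C(n, j) zeta_bar^(j-2)
    asym_1 = gamma;   asym_n = K_n (1 + asym_{n-1}) / (n c1)
    unif_n = max(V(x0)^n, K_n (1 + unif_{n-1}) / (n c1))

The recursion is conservative but valid whenever DD holds with finite
``c3`` and bounded jumps; its slack grows with the order, which is why
bound *validity* (SSA moments never exceeding the table) rather than
tightness is the testable contract.  Without DD2 the table stops at
``n = 1`` (the drift-only bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .drift import (
    DDCertificate,
    _dd_constants,
    conservation_vector,
    evaluate_propensities,
)
from .ergodicity import certificate_lp
from .network import ReactionNetwork

__all__ = [
    "AttractorResult",
    "MomentBoundTable",
    "ClosureAudit",
    "optimal_attractor_unimolecular",
    "optimal_attractor_conserved",
    "optimal_attractor_qneg",
    "optimal_attractor",
    "moment_bounds",
    "light_tail_flags",
    "closure_audit",
    "distance_to_attractor",
]

REL_TOL = 1e-6
MAX_OUTER_ITERS = 120


@dataclass
class AttractorResult:
    v_star: np.ndarray
    c1_star: float
    c2_star: float
    gamma_star: float
    bisection_trace: list = field(default_factory=list)

    @property
    def set_description(self) -> str:
        v = ", ".join(f"{x:.6g}" for x in self.v_star)
        return f"{{x >= 0 : <({v}), x> <= {self.gamma_star:.6g}}}"

    def to_dict(self) -> dict:
        return {
            "v": [float(x) for x in self.v_star],
            "c1": self.c1_star, "c2": self.c2_star, "gamma": self.gamma_star,
            "set": self.set_description,
        }


def _feasible_c1_max(net, lp_kwargs) -> float:
    """Largest decay rate c1 with a feasible certificate (bisection;
    feasibility is monotone decreasing in c1)."""
    if certificate_lp(net, 1e-12, minimize_c2=False, **lp_kwargs) is None:
        return 0.0
    hi = 1.0
    while certificate_lp(net, hi, minimize_c2=False, **lp_kwargs) is not None:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover
            break
    lo = hi / 2.0 if hi > 1.0 else 1e-12
    if hi == 1.0:
        lo = 1e-12
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if certificate_lp(net, mid, minimize_c2=False, **lp_kwargs) is not None:
            lo = mid
        else:
            hi = mid
    return lo


def _optimal_attractor(net: ReactionNetwork, lp_kwargs, label: str) -> AttractorResult:
    c1_max = _feasible_c1_max(net, lp_kwargs)
    if c1_max <= 0:
        raise ValueError(f"not certifiable by the {label} program")
    # the supremum decay rate is often attained (e.g. at the spectral
    # abscissa of the linear drift matrix); test it exactly
    endpoint_candidates = []
    if net.class_tag == "unimolecular":
        from .drift import unimolecular_affine

        absc = -float(np.max(np.linalg.eigvals(unimolecular_affine(net).A).real))
        if absc > 0 and certificate_lp(net, absc, minimize_c2=False,
                                       **lp_kwargs) is not None:
            endpoint_candidates.append(absc)
            c1_max = max(c1_max, absc)
    trace = []

    def F(c1):
        """Objective at requested decay c1, evaluated at the *effective*
        decay rate of the LP solution (exact from the decomposition), so
        the reported gamma is the bound the returned v truly witnesses
        regardless of LP feasibility tolerances."""
        sol = certificate_lp(net, c1, **lp_kwargs)
        if sol is None:
            return math.inf, None
        v, c2 = sol
        _, lin, _, _, _ = _dd_constants(net, v)
        c1_eff = float(np.min(-lin / v))
        if c1_eff <= 0:
            return math.inf, None
        trace.append((c1, c2))
        return c2 / c1_eff, (v, c2, c1_eff)

    # coarse deterministic scan (the objective need not be unimodal in
    # pathological cases), then golden-section refinement of the best cell
    grid = np.unique(np.concatenate([
        np.linspace(c1_max / 40, c1_max, 40),
        np.logspace(math.log10(max(c1_max * 1e-8, 1e-12)), math.log10(c1_max), 20),
    ]))
    vals = [F(c)[0] for c in grid]
    ibest = int(np.argmin(vals))
    lo = grid[max(ibest - 1, 0)]
    hi = grid[min(ibest + 1, len(grid) - 1)]
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    x1 = b - phi * (b - a)
    x2 = a + phi * (b - a)
    f1, f2 = F(x1)[0], F(x2)[0]
    for _ in range(MAX_OUTER_ITERS):
        if (b - a) <= REL_TOL * max(abs(a), abs(b)):
            break
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - phi * (b - a)
            f1 = F(x1)[0]
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + phi * (b - a)
            f2 = F(x2)[0]
    candidates = [0.5 * (a + b), c1_max, grid[ibest]] + endpoint_candidates
    best = (math.inf, None, None)
    for c1 in candidates:
        val, sol = F(c1)
        if val < best[0]:
            best = (val, c1, sol)
    gamma, _, sol = best
    v, c2, c1_eff = sol
    return AttractorResult(v_star=v, c1_star=float(c1_eff), c2_star=float(c2),
                           gamma_star=float(gamma), bisection_trace=trace)


def optimal_attractor_unimolecular(net: ReactionNetwork) -> AttractorResult:
    """Smallest attractive half-space for a unimolecular network
    (inner LP linear in the number of species)."""
    if net.class_tag != "unimolecular":
        raise ValueError("network is not unimolecular")
    return _optimal_attractor(net, {}, "unimolecular")


def optimal_attractor_conserved(net: ReactionNetwork) -> AttractorResult:
    """Optimal attractor with the conservation-cone constraints
    ``S_b.T v = 0`` (bimolecular networks with nonempty V_b)."""
    if conservation_vector(net) is None:
        raise ValueError("V_b is empty: conservation-cone attractor unavailable")
    return _optimal_attractor(net, {"conserve": True}, "conservation-cone")


def optimal_attractor_qneg(net: ReactionNetwork) -> AttractorResult:
    """Optimal attractor with componentwise ``Q(v) <= 0`` constraints
    (O(d^2) constraints; no conservation needed)."""
    return _optimal_attractor(net, {"q_componentwise": True}, "componentwise-Q")


def optimal_attractor(net: ReactionNetwork) -> AttractorResult:
    """Route to the cheapest applicable attractor program."""
    if net.class_tag == "unimolecular":
        return optimal_attractor_unimolecular(net)
    if conservation_vector(net) is not None:
        return optimal_attractor_conserved(net)
    return optimal_attractor_qneg(net)


# ---------------------------------------------------------------------------
# moment-bound tables
# ---------------------------------------------------------------------------

@dataclass
class MomentBoundTable:
    orders: dict            # n -> {"uniform": float, "asymptotic": float}
    c1: float
    c2: float
    c3: float
    zeta_bar: float
    gamma: float
    V0: float
    validity_condition: str

    def uniform(self, n: int) -> float:
        return self.orders[n]["uniform"]

    def asymptotic(self, n: int) -> float:
        return self.orders[n]["asymptotic"]

    def to_dict(self) -> dict:
        return {
            "orders": {str(n): dict(v) for n, v in self.orders.items()},
            "c1": self.c1, "c2": self.c2,
            "c3": None if math.isinf(self.c3) else self.c3,
            "zeta_bar": self.zeta_bar, "gamma": self.gamma,
            "validity_condition": self.validity_condition,
        }


def moment_bounds(cert: DDCertificate, n_max: int, x0) -> MomentBoundTable:
    """Uniform and asymptotic bounds on ``E[<v, X(t)>^n]``, n = 1..n_max.

    Requires a verified DD1; orders above 1 additionally require DD2
    with finite ``c3`` and bounded jumps and use the conservative
    comparison recursion (see module docstring).  Bounds are
    nonincreasing in ``c1``.
    """
    if not cert.dd1_verified:
        raise ValueError("moment bounds require a verified DD1 certificate")
    x0 = np.asarray(x0, dtype=float)
    V0 = float(cert.v @ x0)
    gamma = cert.c2 / cert.c1
    orders = {1: {"uniform": max(V0, gamma), "asymptotic": gamma}}
    hard_max = n_max
    if not (cert.dd2_verified and math.isfinite(cert.c3)
            and math.isfinite(cert.zeta_bar)):
        hard_max = 1
        cond = "DD1 only: table restricted to n = 1 (drift-only bound)"
    else:
        cond = ("valid for every n: Condition DD holds with finite c3 "
                "and bounded jumps")
    for n in range(2, hard_max + 1):
        Kn = n * cert.c2 + 2.0 * cert.c3 * sum(
            math.comb(n, j) * cert.zeta_bar ** (j - 2) for j in range(2, n + 1)
        )
        prev_u = orders[n - 1]["uniform"]
        prev_a = orders[n - 1]["asymptotic"]
        orders[n] = {
            "uniform": max(V0 ** n, Kn * (1.0 + prev_u) / (n * cert.c1)),
            "asymptotic": Kn * (1.0 + prev_a) / (n * cert.c1),
        }
    return MomentBoundTable(
        orders=orders, c1=cert.c1, c2=cert.c2, c3=cert.c3,
        zeta_bar=cert.zeta_bar, gamma=gamma, V0=V0, validity_condition=cond,
    )


def light_tail_flags(cert: DDCertificate) -> dict:
    """Qualitative light-tailedness conclusions.

    Both the uniform-in-time and the stationary distribution are
    light-tailed (the moment generating function exists) when Condition
    DD holds in full: DD1, DD2 with finite ``c3``, bounded jumps.
    """
    ok = bool(cert.dd1_verified and cert.dd2_verified
              and math.isfinite(cert.c3) and math.isfinite(cert.zeta_bar))
    reason = "Condition DD holds with finite c3 and bounded jumps" if ok else (
        "DD2 fails (superlinear diffusivity)" if cert.dd1_verified
        and not cert.dd2_verified else "DD1 not verified")
    return {"uniform_light_tailed": ok, "stationary_light_tailed": ok,
            "reason": reason}


# ---------------------------------------------------------------------------
# moment-closure audit
# ---------------------------------------------------------------------------

@dataclass
class ClosureAudit:
    closed_equilibrium: np.ndarray
    inside_attractor: bool
    error_lower_bound: float
    jacobian_stable: bool
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "closed_equilibrium": [float(x) for x in self.closed_equilibrium],
            "inside_attractor": self.inside_attractor,
            "error_lower_bound": self.error_lower_bound,
            "jacobian_stable": self.jacobian_stable,
            "notes": self.notes,
        }


def _closed_rhs(net: ReactionNetwork):
    """Cumulant-neglect (variance-neglect) closed first-moment ODE.

    Replacing E[x_i x_j] by y_i y_j in the exact first-moment equation
    turns the stochastic falling-factorial propensities into their real
    evaluations, so the closed right-hand side is simply the stochastic
    drift evaluated at the real vector y.
    """
    S = net.stoichiometry_matrix().astype(float)

    def rhs(t, y):
        return S @ evaluate_propensities(net, np.maximum(y, 0.0))

    return rhs


def distance_to_attractor(v, gamma: float, y) -> float:
    """Euclidean distance from ``y`` to ``{x >= 0 : <v, x> <= gamma}``.

    Exact KKT projection: ``x(mu) = max(0, y - mu v)`` with the
    multiplier ``mu >= 0`` found by bisection on the monotone constraint
    residual.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    yp = np.maximum(y, 0.0)
    if float(v @ yp) <= gamma + 1e-15:
        return float(np.linalg.norm(y - yp))
    lo, hi = 0.0, 1.0
    while float(v @ np.maximum(0.0, y - hi * v)) > gamma:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(v @ np.maximum(0.0, y - mid * v)) > gamma:
            lo = mid
        else:
            hi = mid
    x = np.maximum(0.0, y - hi * v)
    return float(np.linalg.norm(y - x))


def closure_audit(net: ReactionNetwork, attractor: AttractorResult,
                  x0=None, closure: str = "cumulant_neglect",
                  t_max: float = 1e4) -> ClosureAudit:
    """Check whether the cumulant-neglect closed system settles inside
    the certified attractive set.

    Integrates the closed first-moment ODE to (near) equilibrium,
    refines by root finding, checks local stability through the
    numerical Jacobian, and reports the distance from the closed
    equilibrium to the attractor as a lower bound on the closure error
    (zero iff the equilibrium lies in the set).
    """
    if closure != "cumulant_neglect":
        raise ValueError("only the cumulant-neglect closure is implemented")
    rhs = _closed_rhs(net)
    y0 = np.zeros(net.d) if x0 is None else np.asarray(x0, dtype=float)
    blow = {"t": None}

    def too_big(t, y):
        return float(np.max(np.abs(y)) - 1e9)
    too_big.terminal = True
    too_big.direction = 1.0

    sol = solve_ivp(rhs, (0.0, t_max), y0, method="LSODA", events=too_big,
                    rtol=1e-10, atol=1e-10)
    if sol.t_events[0].size:
        return ClosureAudit(
            closed_equilibrium=sol.y[:, -1], inside_attractor=False,
            error_lower_bound=math.inf, jacobian_stable=False,
            notes=f"closed system unbounded (escape near t = {sol.t_events[0][0]:.3g})",
        )
    y_eq = fsolve(lambda y: rhs(0.0, y), sol.y[:, -1], full_output=False)
    y_eq = np.maximum(np.asarray(y_eq, dtype=float), 0.0)
    # numerical Jacobian
    d = net.d
    J = np.zeros((d, d))
    h = 1e-6 * np.maximum(1.0, np.abs(y_eq))
    f0 = rhs(0.0, y_eq)
    for j in range(d):
        yp = y_eq.copy()
        yp[j] += h[j]
        J[:, j] = (rhs(0.0, yp) - f0) / h[j]
    stable = bool(np.max(np.linalg.eigvals(J).real) < 0)
    dist = distance_to_attractor(attractor.v_star, attractor.gamma_star, y_eq)
    return ClosureAudit(
        closed_equilibrium=y_eq,
        inside_attractor=bool(dist <= 1e-9 * max(1.0, attractor.gamma_star)),
        error_lower_bound=dist,
        jacobian_stable=stable,
    )
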