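"""Ergodicity certificate searches.

The certificates are sufficient conditions built on Condition DD
(:mod:`ergokit.drift`):

* unimolecular networks -- the linear drift matrix ``A`` is Metzler, and
  Hurwitz stability of ``A`` is *equivalent* to the existence of a
  positive vector ``v`` with ``A.T v < 0``, a linear program;
* robust (interval-rate) unimolecular networks -- the same program on a
  componentwise upper-bound matrix certifies the whole family at once;
* bimolecular networks with a conservation relation for all order-2
  channels (the cone ``V_b``) -- the quadratic drift term vanishes on
  ``V_b`` and the unimolecular program applies with the extra equality
  ``S_b.T v = 0``;
* general bimolecular networks -- componentwise nonpositivity of ``Q(v)``
  (a linear program) or negative definiteness of ``Q(v)`` (a semidefinite
  condition, solved here by eigenvector cutting planes over linear
  programs);
* competitive Lotka-Volterra communities -- diagonal rescaling to a
  negative definite ``Q(v)``, or strict copositivity of ``-Q(v)``;
* scalar networks with higher-order kinetics (Schloegl) -- the weighted
  stochastic drift is a univariate polynomial whose negative leading
  coefficient yields DD1 by lattice maximization.

All searches return honest ``no_certificate_found`` outcomes: the method
provides sufficient conditions only and never claims non-ergodicity.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from . import fixtures as _fixtures
from .drift import (
    BOUNDED,
    MASS_ACTION,
    SCALED_BOUNDED,
    DDCertificate,
    _dd_constants,
    _falling,
    decompose,
    unimolecular_affine,
    verify_dd,
)
from .network import PropensitySpec, Reaction, ReactionNetwork

__all__ = [
    "ErgodicityReport",
    "hurwitz_test",
    "positive_linear_certificate",
    "certificate_lp",
    "negdef_certificate",
    "copositivity_test",
    "detect_bounded_species",
    "reduce_bounded_species",
    "analyze_unimolecular",
    "analyze_robust",
    "analyze_bimolecular_conserved",
    "analyze_bimolecular_general",
    "analyze_lotka_volterra",
    "scalar_polynomial_drift",
    "analyze",
]

EPS_STRICT = 1e-6   # scale-aware strictness margin for v' A < 0 (v >= 1)
TOL_EIG = 1e-9      # Hurwitz margin; |abscissa| below this is "marginal"


@dataclass
class ErgodicityReport:
    verdict: str                       # ergodic | ergodic_robust | no_certificate_found
    method: str
    certificate: DDCertificate | None = None
    moment_conclusion: str = "none"    # all_orders | up_to_order_n | first_order_only | none
    moment_order: int | None = None
    light_tailed: bool = False
    irreducibility_status: str = "unknown"
    attempts: list = field(default_factory=list)
    reduced_species: list | None = None    # free species the certificate lives on
    bounded_species: dict | None = None    # conserved species dropped, with caps
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "method": self.method,
            "certificate": self.certificate.to_dict() if self.certificate else None,
            "moment_conclusion": self.moment_conclusion,
            "moment_order": self.moment_order,
            "light_tailed": self.light_tailed,
            "irreducibility_status": self.irreducibility_status,
            "attempts": self.attempts,
            "reduced_species": self.reduced_species,
            "bounded_species": self.bounded_species,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# linear-algebra primitives
# ---------------------------------------------------------------------------

def hurwitz_test(A, tol_eig: float = TOL_EIG) -> bool:
    """True iff every eigenvalue of ``A`` has real part below ``-tol_eig``."""
    A = np.asarray(A, dtype=float)
    return bool(np.max(np.linalg.eigvals(A).real) < -tol_eig)


def is_metzler(A, tol: float = 1e-12) -> bool:
    A = np.asarray(A, dtype=float)
    off = A - np.diag(np.diag(A))
    return bool(np.min(off) >= -tol)


def positive_linear_certificate(A, eps_strict: float = EPS_STRICT):
    """Positive vector ``v >= 1`` with ``A.T v <= -eps_strict * v``, or None.

    For a Metzler matrix, feasibility is equivalent to Hurwitz stability
    (up to the strictness margin).  Non-Metzler input is rejected since
    the equivalence is not guaranteed there.
    """
    A = np.asarray(A, dtype=float)
    if not is_metzler(A):
        raise ValueError("positive_linear_certificate requires a Metzler matrix")
    d = A.shape[0]
    res = linprog(
        c=np.ones(d),
        A_ub=A.T + eps_strict * np.eye(d),
        b_ub=np.zeros(d),
        bounds=[(1.0, None)] * d,
        method="highs",
    )
    return res.x if res.success else None


# ---------------------------------------------------------------------------
# the certificate linear program (shared by analysis and attractor search)
# ---------------------------------------------------------------------------

def certificate_lp(
    net: ReactionNetwork,
    c1: float,
    *,
    conserve: bool = False,
    q_componentwise: bool = False,
    minimize_c2: bool = True,
):
    """Find ``v >= 1`` with ``lin(v) <= -c1 * v`` (and optional quadratic
    constraints), minimizing the DD1 constant ``c2(v)``.

    Variables are ``v`` plus one auxiliary ``t_k = max(<v, zeta_k>, 0)``
    per bounded channel (the convex envelope of its worst-case drift
    contribution).  With ``conserve`` the equalities ``S_b.T v = 0`` force
    every order-2 channel's weighted jump to vanish; with
    ``q_componentwise`` every entry of ``Q(v)`` is constrained
    nonpositive, which is sufficient for ``x^T Q(v) x <= 0`` on the
    nonnegative orthant.

    Returns ``(v, c2)`` or ``None`` if infeasible.
    """
    dec = decompose(net)
    d = net.d
    n_b = len(dec.bounded)
    nvar = d + n_b
    A_ub, b_ub = [], []
    A_eq, b_eq = [], []

    # decay rows: (M^T v)_i + sum_scaled sup * t_k <= -c1 v_i
    for i in range(d):
        row = np.zeros(nvar)
        row[:d] = dec.M[:, i]           # (M^T v)_i = sum_a v_a M[a, i]
        row[i] += c1
        for kb, (z, sup, scale) in enumerate(dec.bounded):
            if scale == i:
                row[d + kb] += sup
        A_ub.append(row)
        b_ub.append(0.0)

    # t_k >= <v, zeta_k>  (t_k >= 0 via bounds)
    for kb, (z, sup, scale) in enumerate(dec.bounded):
        row = np.zeros(nvar)
        row[:d] = z
        row[d + kb] = -1.0
        A_ub.append(row)
        b_ub.append(0.0)

    if conserve:
        Sb = net.bimolecular_stoichiometry()
        for k in range(Sb.shape[1]):
            row = np.zeros(nvar)
            row[:d] = Sb[:, k]
            A_eq.append(row)
            b_eq.append(0.0)

    if q_componentwise:
        for a in range(d):
            for b_idx in range(a, d):
                coef = dec.Qt[:, a, b_idx]
                if np.any(coef):
                    row = np.zeros(nvar)
                    row[:d] = coef
                    A_ub.append(row)
                    b_ub.append(0.0)

    c = np.zeros(nvar)
    if minimize_c2:
        c[:d] = dec.b
        for kb, (z, sup, scale) in enumerate(dec.bounded):
            if scale is None:
                c[d + kb] = sup
    else:
        c[:d] = 1.0

    bounds = [(1.0, None)] * d + [(0.0, None)] * n_b
    res = linprog(
        c=c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return None
    v = res.x[:d]
    c2 = float(dec.b @ v) + sum(
        sup * max(float(v @ z), 0.0)
        for (z, sup, scale) in dec.bounded
        if scale is None
    )
    return v, c2


def negdef_certificate(
    net: ReactionNetwork,
    eps_sdp: float = 1e-6,
    c1: float = EPS_STRICT,
    max_cuts: int = 300,
):
    """Search for ``v >= 1`` with ``Q(v) <= -eps_sdp * I`` (matrix sense)
    and decaying linear part, by Kelley cutting planes.

    The semidefinite constraint is approximated from outside by the
    linear cuts ``u^T Q(v) u <= -eps_sdp`` for unit vectors ``u``;
    each round adds the top eigenvector of the current ``Q(v)`` until the
    eigenvalue test passes or the LP becomes infeasible (a certificate of
    infeasibility for the relaxation, hence for the SDP).
    """
    dec = decompose(net)
    d = net.d
    cuts = [np.eye(d)[i] for i in range(d)]
    for _ in range(max_cuts):
        n_b = len(dec.bounded)
        nvar = d + n_b
        A_ub, b_ub = [], []
        for i in range(d):
            row = np.zeros(nvar)
            row[:d] = dec.M[:, i]
            row[i] += c1
            for kb, (z, sup, scale) in enumerate(dec.bounded):
                if scale == i:
                    row[d + kb] += sup
            A_ub.append(row)
            b_ub.append(0.0)
        for kb, (z, sup, scale) in enumerate(dec.bounded):
            row = np.zeros(nvar)
            row[:d] = z
            row[d + kb] = -1.0
            A_ub.append(row)
            b_ub.append(0.0)
        for u in cuts:
            row = np.zeros(nvar)
            row[:d] = np.einsum("a,iab,b->i", u, dec.Qt, u)
            A_ub.append(row)
            b_ub.append(-eps_sdp)
        res = linprog(
            c=np.ones(nvar),
            A_ub=np.array(A_ub), b_ub=np.array(b_ub),
            bounds=[(1.0, None)] * d + [(0.0, None)] * n_b,
            method="highs",
        )
        if not res.success:
            return None
        v = res.x[:d]
        Q = dec.Q_of(v)
        lam, vec = np.linalg.eigh((Q + Q.T) / 2.0)
        if lam[-1] <= -eps_sdp * 0.5:
            return v
        cuts.append(vec[:, -1])
    return None


# ---------------------------------------------------------------------------
# copositivity
# ---------------------------------------------------------------------------

def copositivity_test(M, tol: float = 1e-10) -> dict:
    """Decide copositivity of a symmetric matrix (dimension <= 10).

    Minimizes ``x.T M x`` over the probability simplex by enumerating the
    KKT points of every face (supports ``S`` with ``M_S y = mu * 1``,
    ``y > 0``), which is exact for nondegenerate matrices; degenerate
    faces fall through to their sub-faces.  Returns a witness
    ``x >= 0`` with ``x.T M x < 0`` when one exists.
    """
    M = np.asarray(M, dtype=float)
    d = M.shape[0]
    if d > 10:
        raise ValueError("copositivity test limited to dimension <= 10")
    if not np.allclose(M, M.T, atol=1e-12):
        warnings.warn("matrix not symmetric; symmetrizing")
        M = (M + M.T) / 2.0
    scale = max(1.0, float(np.max(np.abs(M))))
    best_val, best_x = math.inf, None
    for r in range(1, d + 1):
        for S in itertools.combinations(range(d), r):
            S = list(S)
            if r == 1:
                val, y = M[S[0], S[0]], np.ones(1)
            else:
                MS = M[np.ix_(S, S)]
                KKT = np.zeros((r + 1, r + 1))
                KKT[:r, :r] = MS
                KKT[:r, r] = -1.0
                KKT[r, :r] = 1.0
                rhs = np.zeros(r + 1)
                rhs[r] = 1.0
                try:
                    sol = np.linalg.solve(KKT, rhs)
                except np.linalg.LinAlgError:
                    continue
                y = sol[:r]
                if np.any(y < -1e-12):
                    continue
                y = np.maximum(y, 0.0)
                val = float(y @ MS @ y)
            if val < best_val:
                best_val = val
                x = np.zeros(d)
                x[S] = y
                best_x = x
    if best_val < -tol * scale:
        return {"copositive": False, "witness": best_x,
                "value": best_val, "method": "face_enumeration"}
    return {"copositive": True, "witness": None,
            "value": best_val, "method": "face_enumeration"}


def strict_copositivity_margin(M, tol: float = 1e-10) -> float:
    """Largest ``delta`` (within bisection tolerance) such that
    ``M - delta * I`` stays copositive; 0 if ``M`` itself is not."""
    if not copositivity_test(M, tol)["copositive"]:
        return 0.0
    hi = float(np.max(np.abs(M))) + 1.0
    if copositivity_test(M - hi * np.eye(M.shape[0]), tol)["copositive"]:
        return hi
    lo = 0.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if copositivity_test(M - mid * np.eye(M.shape[0]), tol)["copositive"]:
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# conserved bounded species and network reduction
# ---------------------------------------------------------------------------

def detect_bounded_species(net: ReactionNetwork, x0) -> dict[str, float]:
    """Species bounded by conservation relations, with their caps.

    Species ``i`` is bounded when some nonnegative combination ``u``
    (``u_i >= 1``) annihilates every stoichiometric vector; then
    ``x_i <= u @ x0`` along every trajectory from ``x0``.  (E.g. gene
    copies: free + bound states sum to the copy number.)
    """
    x0 = np.asarray(x0, dtype=float)
    S = net.stoichiometry_matrix().astype(float)
    caps: dict[str, float] = {}
    for i, name in enumerate(net.species):
        if name in caps:
            continue
        res = linprog(
            c=np.ones(net.d),
            A_eq=S.T, b_eq=np.zeros(net.K),
            bounds=[(1.0, None) if j == i else (0.0, None) for j in range(net.d)],
            method="highs",
        )
        if res.success:
            u = res.x
            total = float(u @ x0)
            for j in range(net.d):
                if u[j] > 1e-9:
                    cap = total / u[j]
                    nm = net.species[j]
                    caps[nm] = min(caps.get(nm, math.inf), cap)
    return caps


def reduce_bounded_species(net: ReactionNetwork, caps: dict[str, float]) -> ReactionNetwork:
    """Project out conserved bounded species, replacing their propensity
    influence by suprema.

    Mass-action channels whose reactants include bounded species are
    relaxed to bounded (or per-capita bounded) channels with supremum
    equal to the rate constant times the falling factorial of the caps.
    The resulting drift is a valid upper envelope on the invariant set,
    so any DD certificate for the reduced network applies to the
    original.
    """
    free = [s for s in net.species if s not in caps]
    red = ReactionNetwork(free, params=dict(net.params),
                          name=(net.name or "net") + "_reduced")
    for r in net.reactions:
        p = r.propensity
        zf = np.array([r.zeta[net.species_index(s)] for s in free], dtype=int)
        if not zf.any():
            continue
        reactants_f = {nm: m for nm, m in p.reactant_multiset.items() if nm in free}
        reactants_b = {nm: m for nm, m in p.reactant_multiset.items() if nm in caps}
        if p.kind == MASS_ACTION:
            if not reactants_b:
                red.add_reaction(r.label, reactants_f,
                                 _products(reactants_f, zf, free), p.rate_constant)
                continue
            env = p.rate_constant
            for nm, m in reactants_b.items():
                env *= _falling(caps[nm], m)
            env = max(env, 0.0)
            order_f = sum(reactants_f.values())
            if order_f == 0:
                red.add_reaction(r.label, {}, _products({}, zf, free),
                                 kind=BOUNDED, sup=env)
            elif order_f == 1:
                (nm,) = reactants_f
                red.add_reaction(r.label, reactants_f,
                                 _products(reactants_f, zf, free),
                                 kind=SCALED_BOUNDED, sup=env, per=nm)
            else:
                raise ValueError(
                    f"reaction {r.label}: cannot reduce a channel that is "
                    "second order in unbounded species"
                )
        elif p.kind == BOUNDED:
            red.add_reaction(r.label, reactants_f,
                             _products(reactants_f, zf, free),
                             kind=BOUNDED, sup=p.sup_bound)
        else:  # scaled_bounded
            if p.scale_species in caps:
                red.add_reaction(r.label, reactants_f,
                                 _products(reactants_f, zf, free),
                                 kind=BOUNDED,
                                 sup=p.sup_bound * caps[p.scale_species])
            else:
                red.add_reaction(r.label, reactants_f,
                                 _products(reactants_f, zf, free),
                                 kind=SCALED_BOUNDED, sup=p.sup_bound,
                                 per=p.scale_species)
    return red


def _products(reactants: dict[str, int], zeta, species) -> dict[str, int]:
    prods = {}
    for i, s in enumerate(species):
        n = int(zeta[i]) + reactants.get(s, 0)
        if n > 0:
            prods[s] = n
    return prods


# ---------------------------------------------------------------------------
# analysis entry points
# ---------------------------------------------------------------------------

def _report_from_v(net, v, method, *, moment="all_orders", order=None,
                   irreducibility="asserted_by_user", c1_request=None,
                   attempts=None) -> ErgodicityReport:
    cert = verify_dd(net, v, c1_request=c1_request)
    verdict = "ergodic" if cert.dd1_verified else "no_certificate_found"
    if not cert.dd1_verified:
        moment, order = "none", None
    light = cert.dd1_verified and cert.dd2_verified and math.isfinite(cert.zeta_bar)
    return ErgodicityReport(
        verdict=verdict, method=method, certificate=cert,
        moment_conclusion=moment if cert.dd1_verified else "none",
        moment_order=order,
        light_tailed=light,
        irreducibility_status=irreducibility if verdict == "ergodic" else "unknown",
        attempts=attempts or [],
    )


def analyze_unimolecular(net: ReactionNetwork, *,
                         irreducibility: str = "asserted_by_user") -> ErgodicityReport:
    """Ergodicity of a unimolecular network via the Metzler-matrix linear
    program; success implies boundedness and global convergence of
    moments of every order."""
    if net.class_tag != "unimolecular":
        raise ValueError(f"network is {net.class_tag}, not unimolecular")
    aff = unimolecular_affine(net)
    v = positive_linear_certificate(aff.A)
    if v is None:
        return ErgodicityReport(
            verdict="no_certificate_found", method="unimolecular_lp",
            attempts=[{"method": "unimolecular_lp", "outcome": "infeasible"}],
            irreducibility_status="unknown",
        )
    return _report_from_v(net, v, "unimolecular_lp", irreducibility=irreducibility)


def analyze_robust(net: ReactionNetwork, *,
                   irreducibility: str = "asserted_by_user") -> ErgodicityReport:
    """Robust ergodicity over declared rate intervals.

    Builds the componentwise upper-bound matrix of the interval family
    ``A(theta)`` (always a valid Metzler bound, since each rate enters
    each entry with a fixed sign) and runs the positive-certificate
    program on it.  When the bound is attained by a single parameter
    choice the program is *equivalent* to robust Hurwitz stability of
    the family; otherwise a feasible certificate is still sufficient,
    and an infeasible one is reported as ``bound_matrix_unavailable``
    since the family may still be robustly stable.
    """
    if net.class_tag != "unimolecular":
        raise ValueError("robust analysis implemented for unimolecular networks")
    aff = unimolecular_affine(net)
    A_bar = aff.A.copy()
    attained = True
    for r in net.reactions:
        p = r.propensity
        if r.label not in net.rate_intervals or p.kind != MASS_ACTION:
            continue
        lo, hi = net.rate_intervals[r.label]
        if p.order != 1:
            continue  # zero-order rates only shift b, which stays finite
        (nm, _), = p.reactant_multiset.items()
        j = net.species_index(nm)
        z = r.zeta.astype(float)
        # entrywise sup: hi where the rate pushes the entry up, lo where down
        A_bar[:, j] += np.where(z > 0, hi, lo) * z - p.rate_constant * z
        if np.any(z > 0) and np.any(z < 0) and hi > lo:
            attained = False
    v = positive_linear_certificate(A_bar)
    if v is not None:
        rep = _report_from_v(net, _certify_against_bar(net, v), "robust_lp",
                             irreducibility=irreducibility)
        rep.verdict = "ergodic_robust" if rep.verdict == "ergodic" else rep.verdict
        rep.notes = "bound matrix attained" if attained else (
            "bound matrix is an unattained entrywise envelope (sufficiency only)")
        return rep
    return ErgodicityReport(
        verdict="no_certificate_found" if attained else "bound_matrix_unavailable",
        method="robust_lp", irreducibility_status="unknown",
        attempts=[{"method": "robust_lp", "outcome": "infeasible"}],
    )


def _certify_against_bar(net, v):
    # the certificate vector transfers to the nominal network unchanged
    return v


def analyze_bimolecular_conserved(net: ReactionNetwork, *,
                                  irreducibility: str = "asserted_by_user") -> ErgodicityReport:
    """Ergodicity through the conservation cone V_b: a single linear
    program over ``{v >= 1, S_b.T v = 0, lin(v) <= -eps v}``."""
    from .drift import conservation_vector

    if conservation_vector(net) is None:
        return ErgodicityReport(
            verdict="prerequisite_failed", method="conserved_lp",
            notes="V_b empty: no conservation relation for the bimolecular channels",
            attempts=[{"method": "conserved_lp", "outcome": "V_b empty"}],
        )
    sol = certificate_lp(net, EPS_STRICT, conserve=True)
    if sol is None:
        return ErgodicityReport(
            verdict="no_certificate_found", method="conserved_lp",
            attempts=[{"method": "conserved_lp", "outcome": "infeasible"}],
        )
    return _report_from_v(net, sol[0], "conserved_lp", irreducibility=irreducibility)


def analyze_bimolecular_general(net: ReactionNetwork, mode: str = "componentwise_lp", *,
                                irreducibility: str = "asserted_by_user") -> ErgodicityReport:
    """General bimolecular certificates (no conservation needed).

    ``componentwise_lp``: every entry of ``Q(v)`` nonpositive plus linear
    decay -- sufficient for drift negativity on the orthant, one LP.
    ``negdef_sdp``: ``Q(v)`` negative definite via eigenvector cutting
    planes.  The recorded moment order (1 and 2 respectively) is the
    conservative reading of what the quadratic certificate supports.
    """
    if mode == "componentwise_lp":
        sol = certificate_lp(net, EPS_STRICT, q_componentwise=True)
        if sol is None:
            return ErgodicityReport(
                verdict="no_certificate_found", method="componentwise_lp",
                attempts=[{"method": "componentwise_lp", "outcome": "infeasible"}],
            )
        return _report_from_v(net, sol[0], "componentwise_lp",
                              moment="up_to_order_n", order=1,
                              irreducibility=irreducibility)
    if mode == "negdef_sdp":
        v = negdef_certificate(net)
        if v is None:
            return ErgodicityReport(
                verdict="no_certificate_found", method="negdef_sdp",
                attempts=[{"method": "negdef_sdp", "outcome": "infeasible"}],
            )
        return _report_from_v(net, v, "negdef_sdp",
                              moment="up_to_order_n", order=2,
                              irreducibility=irreducibility)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Lotka-Volterra template
# ---------------------------------------------------------------------------

def _match_lv_template(net: ReactionNetwork):
    """Classify reactions as immigration/reproduction/competition/death;
    raise on anything else."""
    d = net.d
    comp = np.zeros((d, d))
    has_comp = False
    for r in net.reactions:
        p = r.propensity
        if p.kind != MASS_ACTION:
            raise ValueError("Lotka-Volterra template requires mass-action kinetics")
        z = r.zeta
        order = p.order
        if order == 0 and np.sum(z) == 1 and np.all(z >= 0):
            continue  # immigration
        if order == 1:
            (nm, _), = p.reactant_multiset.items()
            i = net.species_index(nm)
            ok_rep = z[i] == 1 and np.sum(np.abs(z)) == 1
            ok_death = z[i] == -1 and np.sum(np.abs(z)) == 1
            if not (ok_rep or ok_death):
                raise ValueError(f"reaction {r.label} outside the LV template")
            continue
        if order == 2:
            idx = [(net.species_index(nm), m) for nm, m in p.reactant_multiset.items()]
            if len(idx) == 1:  # 2 Si -> Si
                i = idx[0][0]
                if not (z[i] == -1 and np.sum(np.abs(z)) == 1):
                    raise ValueError(f"reaction {r.label} outside the LV template")
                comp[i, i] += p.rate_constant
            else:  # Si + Sj -> Sj (kills the species that decreases)
                (i, _), (j, _) = idx
                if z[i] == -1 and z[j] == 0:
                    comp[i, j] += p.rate_constant
                elif z[j] == -1 and z[i] == 0:
                    comp[j, i] += p.rate_constant
                else:
                    raise ValueError(f"reaction {r.label} outside the LV template")
            has_comp = True
            continue
        raise ValueError(f"reaction {r.label} outside the LV template")
    return comp, has_comp


def analyze_lotka_volterra(net: ReactionNetwork, *,
                           irreducibility: str = "asserted_by_user") -> ErgodicityReport:
    """Competitive Lotka-Volterra certificate.

    Route (a): diagonal weights making ``Q(v)`` negative definite
    (eigenvector cutting planes); route (b): weights making ``-Q(v)``
    strictly copositive (tested exactly by face enumeration), which
    bounds the quadratic by ``-delta * |x|^2`` on the orthant.  Either
    way the net reproduction rate is absorbed by quadratic domination.
    """
    comp, has_comp = _match_lv_template(net)
    if not has_comp:
        return ErgodicityReport(
            verdict="no_certificate_found", method="lv",
            attempts=[{"method": "lv", "outcome": "no competition channels"}],
        )
    attempts = []
    # route (a): Q(v) negative definite (linear decay not required; the
    # quadratic absorbs reproduction).  Use cutting planes without decay rows.
    v = _lv_negdef(net)
    if v is not None:
        rep = _report_from_v(net, v, "lv_diagonal_negdef",
                             moment="up_to_order_n", order=2,
                             irreducibility=irreducibility)
        if rep.verdict == "ergodic":
            rep.attempts = attempts + [{"method": "lv_diagonal_negdef", "outcome": "ok"}]
            rep.moment_conclusion = "first_order_only" if not rep.certificate.dd2_verified else "up_to_order_n"
            return rep
    attempts.append({"method": "lv_diagonal_negdef", "outcome": "infeasible"})
    # route (b): strict copositivity of -Q(v) on a small weight grid
    dec = decompose(net)
    for v in _weight_grid(net.d):
        Q = dec.Q_of(v)
        delta = strict_copositivity_margin(-Q)
        if delta > 1e-9:
            rep = _report_from_v(net, v, "lv_copositive",
                                 moment="first_order_only", order=1,
                                 irreducibility=irreducibility)
            if rep.verdict == "ergodic":
                rep.attempts = attempts + [{"method": "lv_copositive", "outcome": "ok"}]
                return rep
    attempts.append({"method": "lv_copositive", "outcome": "no weight found"})
    return ErgodicityReport(verdict="no_certificate_found", method="lv",
                            attempts=attempts)


def _lv_negdef(net):
    """Cutting-plane search for v >= 1 with Q(v) negative definite
    (no linear decay constraint)."""
    dec = decompose(net)
    d = net.d
    if not np.any(dec.Qt):
        return None
    cuts = [np.eye(d)[i] for i in range(d)]
    eps = 1e-6
    for _ in range(200):
        A_ub = []
        b_ub = []
        for u in cuts:
            A_ub.append(np.einsum("a,iab,b->i", u, dec.Qt, u))
            b_ub.append(-eps)
        res = linprog(c=np.ones(d), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(1.0, None)] * d, method="highs")
        if not res.success:
            return None
        v = res.x
        Q = dec.Q_of(v)
        lam, vec = np.linalg.eigh((Q + Q.T) / 2.0)
        if lam[-1] <= -eps * 0.5:
            return v
        cuts.append(vec[:, -1])
    return None


def _weight_grid(d, n=8):
    if d == 1:
        yield np.ones(1)
        return
    grids = [np.logspace(-1.5, 1.5, n) for _ in range(d - 1)]
    for combo in itertools.product(*grids):
        v = np.array((1.0,) + combo)
        yield v / v.min()


# ---------------------------------------------------------------------------
# scalar polynomial route (general mass-action, single species)
# ---------------------------------------------------------------------------

def scalar_polynomial_drift(net: ReactionNetwork, v=None,
                            c1: float | None = None) -> DDCertificate:
    """DD1 for a single-species network with arbitrary mass-action orders.

    The weighted stochastic drift is a univariate polynomial in the
    count; a strictly negative leading coefficient gives DD1 for *any*
    ``c1 > 0`` with ``c2 = max_x (drift(x) + c1 * v * x)``, computed by
    isolating the real roots of the derivative.  The diffusivity is
    superlinear whenever an order >= 2 channel moves the state, so
    ``c3 = inf`` and nothing is claimed beyond first-order convergence.
    """
    if net.d != 1:
        raise ValueError(
            "scalar polynomial route requires a single species (multivariate "
            "drifts are not collapsible in general)"
        )
    v1 = float(np.asarray(v).ravel()[0]) if v is not None else 1.0
    if v1 <= 0:
        raise ValueError("v must be positive")
    # weighted drift polynomial in x (stochastic convention)
    coeffs = np.zeros(5)  # up to x^4 won't occur; orders <= 3 -> degree 3
    sup_extra = 0.0
    zeta_bar = 0.0
    superlinear = False
    c3_const, c3_lin = 0.0, 0.0
    for r in net.reactions:
        p = r.propensity
        w = v1 * float(r.zeta[0])
        zeta_bar = max(zeta_bar, abs(w))
        if p.kind != MASS_ACTION:
            if w > 0:
                sup_extra += p.sup_bound * w
            c3_const += p.sup_bound * w * w
            continue
        m = p.order
        k = p.rate_constant
        # falling factorial x(x-1)...(x-m+1)/m! expanded
        if m == 0:
            poly = np.array([1.0])
        elif m == 1:
            poly = np.array([0.0, 1.0])
        elif m == 2:
            poly = np.array([0.0, -0.5, 0.5])
        else:
            poly = np.array([0.0, 2.0, -3.0, 1.0]) / 6.0
        contrib = k * w * poly
        coeffs[: len(contrib)] += contrib
        if abs(w) > 0:
            if m >= 2:
                superlinear = True
            elif m == 1:
                c3_lin += k * w * w
            else:
                c3_const += k * w * w
    deg = int(np.max(np.nonzero(np.abs(coeffs) > 0)[0])) if np.any(coeffs) else 0
    lead = coeffs[deg]
    if deg == 0 or lead >= 0:
        return DDCertificate(v=np.array([v1]), c1=0.0, c2=0.0, c3=math.inf,
                             gamma=math.inf, zeta_bar=zeta_bar,
                             dd1_verified=False, dd2_verified=False,
                             notes="nonnegative leading drift coefficient")
    c1 = float(c1) if c1 is not None and c1 > 0 else 1.0
    # g(x) = drift(x) + sup_extra + c1 * v1 * x ; maximize over the lattice
    g = coeffs.copy()
    g[0] += sup_extra
    g[1] += c1 * v1
    dg = np.polynomial.polynomial.polyder(g[: deg + 1])
    crit = [0.0]
    roots = np.polynomial.polynomial.polyroots(dg)
    for rt in roots:
        if abs(rt.imag) < 1e-9 and rt.real > 0:
            crit += [math.floor(rt.real), math.ceil(rt.real)]
    c2 = max(
        float(np.polynomial.polynomial.polyval(x, g[: deg + 1]))
        for x in crit if x >= 0
    )
    c2 = max(c2, 0.0)
    if superlinear:
        c3 = math.inf
    else:
        c3 = max(c3_const, c3_lin / v1)
    return DDCertificate(
        v=np.array([v1]), c1=c1, c2=c2, c3=c3, gamma=c2 / c1,
        zeta_bar=zeta_bar, dd1_verified=True,
        dd2_verified=bool(math.isfinite(c3)),
        notes="scalar polynomial route",
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def analyze(net: ReactionNetwork, x0=None, *,
            assume_irreducible: bool = True,
            try_modes: tuple = ("conserved", "componentwise", "negdef", "lv"),
            ) -> ErgodicityReport:
    """Route a network through the certificate ladder.

    Conserved bounded species (gene states etc.) are detected from the
    initial state and projected out first; the ladder then tries, in
    order, the unimolecular program, the conservation-cone program, the
    componentwise and negative-definite quadratic programs, the
    Lotka-Volterra template and the scalar polynomial route.  The first
    success wins; the full attempt trace is returned either way.
    """
    irr = "asserted_by_user" if assume_irreducible else "unknown"
    attempts = []
    caps: dict[str, float] = {}
    if x0 is None and net.name in _fixtures.FIXTURES:
        x0 = _fixtures.default_initial_state(net)
    if x0 is not None:
        caps = detect_bounded_species(net, x0)
    work = net
    if caps:
        if len(caps) == net.d:
            return ErgodicityReport(
                verdict="ergodic" if assume_irreducible else "no_certificate_found",
                method="finite_state_space",
                moment_conclusion="all_orders",
                light_tailed=True,
                irreducibility_status=irr,
                bounded_species=caps,
                notes="every species bounded by conservation: finite state space",
            )
        work = reduce_bounded_species(net, caps)

    def _finish(rep: ErgodicityReport) -> ErgodicityReport:
        rep.attempts = attempts + rep.attempts
        if caps:
            rep.bounded_species = caps
            rep.reduced_species = list(work.species)
        return rep

    tag = work.class_tag
    if tag == "unimolecular":
        rep = analyze_unimolecular(work, irreducibility=irr)
        rep.method = "unimolecular_lp"
        return _finish(rep)
    if tag == "bimolecular":
        if "conserved" in try_modes:
            rep = analyze_bimolecular_conserved(work, irreducibility=irr)
            if rep.verdict == "ergodic":
                return _finish(rep)
            attempts += rep.attempts
        if "componentwise" in try_modes:
            rep = analyze_bimolecular_general(work, "componentwise_lp",
                                              irreducibility=irr)
            if rep.verdict == "ergodic":
                return _finish(rep)
            attempts += rep.attempts
        if "negdef" in try_modes:
            rep = analyze_bimolecular_general(work, "negdef_sdp",
                                              irreducibility=irr)
            if rep.verdict == "ergodic":
                return _finish(rep)
            attempts += rep.attempts
        if "lv" in try_modes:
            try:
                rep = analyze_lotka_volterra(work, irreducibility=irr)
                if rep.verdict == "ergodic":
                    return _finish(rep)
                attempts += rep.attempts
            except ValueError:
                attempts.append({"method": "lv", "outcome": "template mismatch"})
        return _finish(ErgodicityReport(verdict="no_certificate_found",
                                        method="ladder_exhausted"))
    # general mass-action: scalar polynomial route
    if work.d == 1:
        cert = scalar_polynomial_drift(work)
        if cert.dd1_verified:
            return _finish(ErgodicityReport(
                verdict="ergodic", method="scalar_polynomial",
                certificate=cert,
                moment_conclusion="first_order_only" if not cert.dd2_verified else "all_orders",
                light_tailed=cert.dd2_verified,
                irreducibility_status=irr,
            ))
        attempts.append({"method": "scalar_polynomial",
                         "outcome": cert.notes or "infeasible"})
    else:
        attempts.append({"method": "scalar_polynomial",
                         "outcome": "multivariate order-3 network not collapsible"})
    return _finish(ErgodicityReport(verdict="no_certificate_found",
                                    method="ladder_exhausted"))
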