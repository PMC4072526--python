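"""Exact decomposition of the weighted drift and verification of the
drift-diffusivity condition (Condition DD).

For a positive weight vector ``v`` the process ``<v, X(t)>`` has drift
``sum_k lambda_k(x) <v, zeta_k>`` and diffusivity
``sum_k lambda_k(x) <v, zeta_k>^2``.  Condition DD asks for constants
``c1 > 0``, ``c2 >= 0`` (DD1) and ``c3 >= 0`` (DD2) with::

    <v, drift(x)>  <=  c2 - c1 * <v, x>          for all states x   (DD1)
    diffusivity(x) <=  c3 * (1 + <v, x>)         for all states x   (DD2)

DD1 with irreducibility certifies exponential ergodicity; DD1 + DD2 with
bounded jumps additionally give moment bounds of every order and
light-tailedness.

For mass-action networks of order <= 2 the weighted drift is *exactly* a
quadratic form::

    <v, drift(x)> = x^T Q(v) x + lin(v)^T x + const(v)

with ``Q(v) = sum_i v_i Q_i`` symmetric and linear in ``v``.  The
stochastic propensity of a homodimerization ``2 S_i -> ...`` is
``kappa x_i (x_i - 1) / 2``: its quadratic monomial ``kappa x_i^2 / 2``
enters ``Q`` while the falling-factorial correction ``-kappa x_i / 2``
is folded into the linear term, so certificates hold for the true
stochastic drift rather than its deterministic surrogate.

Bounded-propensity channels are not part of the polynomial identity; they
are retained symbolically and enter the DD constants through their
suprema: a bounded channel with ``<v, zeta> <= 0`` only improves the
drift and is dropped from the DD1 upper bound, one with ``<v, zeta> > 0``
contributes ``sup * <v, zeta>`` to ``c2`` (or, for per-capita bounded
channels, to the linear coefficient of the scaling species).  For DD2
they always contribute ``sup * <v, zeta>^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import BOUNDED, MASS_ACTION, SCALED_BOUNDED, ReactionNetwork

__all__ = [
    "AffineDrift",
    "QuadraticDrift",
    "DDCertificate",
    "evaluate_propensities",
    "drift_vector",
    "unimolecular_affine",
    "quadratic_drift",
    "diffusivity",
    "conservation_vector",
    "verify_dd",
    "audit_certificate",
]

#: entries of Q(v) below this magnitude (relative to |v|) count as zero
_W_TOL = 1e-9


# ---------------------------------------------------------------------------
# propensity evaluation (simulation-grade, needs eval hints for bounded kinds)
# ---------------------------------------------------------------------------

_SAFE_FUNCS = {"exp": math.exp, "log": math.log, "sqrt": math.sqrt,
               "min": min, "max": max, "abs": abs}


def _hint_function(net: ReactionNetwork, expr: str):
    code = compile(expr.replace("^", "**"), "<eval_hint>", "eval")
    names = list(net.species)

    def f(x):
        env = dict(zip(names, x))
        env.update(net.params if all(isinstance(v, (int, float)) for v in net.params.values()) else {})
        env.update(_SAFE_FUNCS)
        return float(eval(code, {"__builtins__": {}}, env))

    return f


def _falling(x: float, m: int) -> float:
    if m == 0:
        return 1.0
    if m == 1:
        return x
    if m == 2:
        return x * (x - 1.0) / 2.0
    return x * (x - 1.0) * (x - 2.0) / 6.0


def evaluate_propensities(net: ReactionNetwork, x) -> np.ndarray:
    """Propensities ``lambda_k(x)`` under the stochastic convention.

    Mass-action channels use falling factorials; bounded channels are
    evaluated through their ``eval_hint`` (an error if absent -- analysis
    paths must use the supremum instead) and clipped to zero whenever a
    declared reactant is below its multiplicity.
    """
    x = np.asarray(x, dtype=float)
    lam = np.zeros(net.K)
    for k, r in enumerate(net.reactions):
        p = r.propensity
        insufficient = any(
            x[net.species_index(nm)] < m for nm, m in p.reactant_multiset.items()
        )
        if insufficient:
            continue
        if p.kind == MASS_ACTION:
            a = p.rate_constant
            for nm, m in p.reactant_multiset.items():
                a *= _falling(x[net.species_index(nm)], m)
            lam[k] = a
        else:
            if p.eval_hint is None:
                raise ValueError(
                    f"reaction {r.label}: bounded propensity has no eval_hint; "
                    "analysis paths must use sup_bound"
                )
            f = getattr(p, "_hint_fn", None)
            if f is None:
                f = _hint_function(net, p.eval_hint)
                p._hint_fn = f
            lam[k] = max(0.0, f(x))
    return lam


def polynomial_propensities(net: ReactionNetwork, y, convention: str = "stochastic",
                            clip: bool = True) -> np.ndarray:
    """Propensities evaluated as smooth polynomials of a *real* state.

    ``stochastic`` uses falling factorials (the cumulant-neglect closed
    moment equations), ``deterministic`` plain monomials ``kappa * y^m``
    (the reaction-rate equations).  No reactant-sufficiency clipping is
    applied; ``clip`` floors the result at zero.
    """
    y = np.asarray(y, dtype=float)
    lam = np.zeros(net.K)
    for k, r in enumerate(net.reactions):
        p = r.propensity
        if p.kind == MASS_ACTION:
            a = p.rate_constant
            for nm, m in p.reactant_multiset.items():
                yi = y[net.species_index(nm)]
                a *= yi ** m / math.factorial(m) if convention == "deterministic" \
                    else _falling(yi, m)
            lam[k] = a
        else:
            if p.eval_hint is None:
                raise ValueError(
                    f"reaction {r.label}: bounded propensity has no eval_hint"
                )
            f = getattr(p, "_hint_fn", None)
            if f is None:
                f = _hint_function(net, p.eval_hint)
                p._hint_fn = f
            lam[k] = f(y)
    return np.maximum(lam, 0.0) if clip else lam


def drift_vector(net: ReactionNetwork, x) -> np.ndarray:
    """``sum_k lambda_k(x) zeta_k`` -- the exact finite drift sum."""
    lam = evaluate_propensities(net, x)
    if net.K == 0:
        return np.zeros(net.d)
    return net.stoichiometry_matrix() @ lam


# ---------------------------------------------------------------------------
# symbolic decomposition
# ---------------------------------------------------------------------------

@dataclass
class AffineDrift:
    """Affine (upper-envelope) drift ``A x + b`` of a unimolecular network.

    Exact when all channels are mass-action of order <= 1; bounded
    channels enter ``b`` (or, per-capita bounded, ``A``) through their
    suprema, with drift-improving parts dropped.  ``A`` is Metzler for
    any valid unimolecular network.
    """

    A: np.ndarray
    b: np.ndarray


@dataclass
class QuadraticDrift:
    """Tensor form of the order-<=2 weighted-drift identity.

    ``Q(v) = einsum('i,iab->ab', v, Qt)`` is symmetric for every ``v``;
    ``lin(v) = M.T @ v``; ``const(v) = b @ v``.  Bounded channels are
    carried separately as ``(zeta, sup, scale_index)`` triples.
    """

    Qt: np.ndarray  # (d, d, d)
    M: np.ndarray   # (d, d)
    b: np.ndarray   # (d,)
    bounded: list = field(default_factory=list)

    def Q_of(self, v) -> np.ndarray:
        return np.einsum("i,iab->ab", np.asarray(v, dtype=float), self.Qt)


def decompose(net: ReactionNetwork) -> QuadraticDrift:
    """Build the exact polynomial decomposition (mass-action order <= 2)."""
    d = net.d
    Qt = np.zeros((d, d, d))
    M = np.zeros((d, d))
    b = np.zeros(d)
    bounded = []
    for r in net.reactions:
        p = r.propensity
        z = r.zeta.astype(float)
        if p.kind == BOUNDED:
            bounded.append((z, float(p.sup_bound), None))
            continue
        if p.kind == SCALED_BOUNDED:
            bounded.append((z, float(p.sup_bound), net.species_index(p.scale_species)))
            continue
        order = p.order
        kappa = p.rate_constant
        if order == 0:
            b += kappa * z
        elif order == 1:
            (nm, _), = p.reactant_multiset.items()
            M[:, net.species_index(nm)] += kappa * z
        elif order == 2:
            idx = [(net.species_index(nm), m) for nm, m in p.reactant_multiset.items()]
            if len(idx) == 1:  # homodimer 2 S_i
                i = idx[0][0]
                for a in range(d):
                    Qt[a, i, i] += kappa * z[a] / 2.0
                M[:, i] -= kappa * z / 2.0
            else:  # hetero S_i + S_j
                (i, _), (j, _) = idx
                for a in range(d):
                    Qt[a, i, j] += kappa * z[a] / 2.0
                    Qt[a, j, i] += kappa * z[a] / 2.0
        else:
            raise ValueError(
                f"reaction {r.label}: order-{order} channel has no quadratic "
                "decomposition; use the scalar polynomial route"
            )
    return QuadraticDrift(Qt=Qt, M=M, b=b, bounded=bounded)


def unimolecular_affine(net: ReactionNetwork) -> AffineDrift:
    """Affine drift ``(A, b)`` of a unimolecular network; ``A`` is Metzler."""
    if net.class_tag != "unimolecular":
        raise ValueError(
            f"network is {net.class_tag}, not unimolecular; use quadratic_drift"
        )
    dec = decompose(net)
    A = dec.M.copy()
    b = dec.b.copy()
    for z, sup, scale in dec.bounded:
        if scale is None:
            b += sup * np.maximum(z, 0.0)
        else:
            A[:, scale] += sup * np.maximum(z, 0.0)
    return AffineDrift(A=A, b=b)


def quadratic_drift(net: ReactionNetwork, v) -> tuple[np.ndarray, np.ndarray, float]:
    """``(Q(v), linear, const)`` with the identity
    ``<v, drift(x)> = x.T Q(v) x + linear @ x + const`` exact for
    mass-action channels of order <= 2 (bounded channels excluded)."""
    if net.class_tag not in ("unimolecular", "bimolecular"):
        raise ValueError(
            "order-3 channel present: no quadratic decomposition; "
            "use the scalar polynomial route"
        )
    v = np.asarray(v, dtype=float)
    dec = decompose(net)
    return dec.Q_of(v), dec.M.T @ v, float(dec.b @ v)


def diffusivity(net: ReactionNetwork, v, x) -> float:
    """``sum_k lambda_k(x) <v, zeta_k>^2`` (exact; hints required for
    bounded channels)."""
    v = np.asarray(v, dtype=float)
    if not np.all(v > 0):
        raise ValueError("weight vector v must be positive")
    lam = evaluate_propensities(net, x)
    w = net.stoichiometry_matrix().T @ v if net.K else np.zeros(0)
    return float(lam @ (w ** 2))


def conservation_vector(net: ReactionNetwork, strict_positive: bool = True):
    """A weight vector in the bimolecular conservation cone V_b.

    Solves ``{v >= 1, S_b.T v = 0}`` by linear programming and returns a
    vector annihilating every order-2 stoichiometric vector, or ``None``
    when the cone is empty (equivalent to the absence of a conservation
    relation for the bimolecular channels; emptiness is a result, not an
    error).
    """
    Sb = net.bimolecular_stoichiometry()
    d = net.d
    lb = 1.0 if strict_positive else 0.0
    if Sb.shape[1] == 0:
        return np.ones(d)
    res = linprog(
        c=np.ones(d),
        A_eq=Sb.T.astype(float),
        b_eq=np.zeros(Sb.shape[1]),
        bounds=[(lb, None)] * d,
        method="highs",
    )
    if not res.success:
        return None
    v = res.x
    # polish: project back onto the exact null space of S_b^T
    from scipy.linalg import null_space

    N = null_space(Sb.T.astype(float))
    if N.size:
        v = N @ (N.T @ v)
    if np.any(v < lb - 1e-9):
        return None
    return np.maximum(v, lb if lb > 0 else 0.0)


# ---------------------------------------------------------------------------
# Condition DD verification
# ---------------------------------------------------------------------------

@dataclass
class DDCertificate:
    """A weight vector with the Condition-DD constants it witnesses.

    ``gamma = c2 / c1`` is the asymptotic first-order bound on
    ``E[<v, X(t)>]``; ``zeta_bar`` is the largest weighted jump size.
    """

    v: np.ndarray
    c1: float
    c2: float
    c3: float
    gamma: float
    zeta_bar: float
    dd1_verified: bool
    dd2_verified: bool
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "v": [float(x) for x in self.v],
            "c1": self.c1, "c2": self.c2,
            "c3": None if math.isinf(self.c3) else self.c3,
            "gamma": None if math.isinf(self.gamma) else self.gamma,
            "zeta_bar": self.zeta_bar,
            "dd1_verified": self.dd1_verified,
            "dd2_verified": self.dd2_verified,
            "notes": self.notes,
        }


def _dd_constants(net: ReactionNetwork, v: np.ndarray):
    """Assemble (Q(v), lin(v), const, c3, zeta_bar) incl. bounded channels."""
    dec = decompose(net)
    Q = dec.Q_of(v)
    lin = dec.M.T @ v
    const = float(dec.b @ v)

    # diffusivity as an affine envelope c3_const + c3_coef @ x where possible
    c3_const = 0.0
    c3_coef = np.zeros(net.d)
    superlinear = False
    zeta_bar = 0.0
    for r in net.reactions:
        p = r.propensity
        w = float(v @ r.zeta)
        zeta_bar = max(zeta_bar, abs(w))
        if p.kind == BOUNDED:
            if w > 0:
                const += p.sup_bound * w
            c3_const += p.sup_bound * w * w
        elif p.kind == SCALED_BOUNDED:
            j = net.species_index(p.scale_species)
            if w > 0:
                lin[j] += p.sup_bound * w
            c3_coef[j] += p.sup_bound * w * w
        else:
            order = p.order
            if w * w <= (_W_TOL * max(1.0, float(np.max(np.abs(v))))) ** 2:
                continue  # conserved channel: no diffusivity contribution
            if order == 0:
                c3_const += p.rate_constant * w * w
            elif order == 1:
                (nm, _), = p.reactant_multiset.items()
                c3_coef[net.species_index(nm)] += p.rate_constant * w * w
            else:
                superlinear = True
    if superlinear:
        c3 = math.inf
    else:
        c3 = max(c3_const, float(np.max(c3_coef / v)) if net.d else 0.0)
    return Q, lin, const, c3, zeta_bar


def verify_dd(net: ReactionNetwork, v, c1_request: float | None = None) -> DDCertificate:
    """Verify Condition DD for a given positive weight vector.

    DD1 is established either linearly (every component of ``lin(v)``
    strictly negative, with ``c1 = min_i(-lin_i / v_i)`` -- the tightest
    constant on the nonnegative orthant, attained along coordinate rays)
    or through quadratic domination (all entries of ``Q(v)`` nonpositive
    with strictly negative diagonal wherever the linear part fails to
    decay, each coordinate's quadratic maximum absorbed into ``c2``).
    DD2 computes the minimal ``c3`` coefficientwise from the affine
    diffusivity envelope; a superlinear diffusivity yields ``c3 = inf``
    and ``dd2_verified = False``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (net.d,) or not np.all(v > 0):
        raise ValueError("v must be a positive vector of length d")
    if net.class_tag == "general_mass_action":
        from .ergodicity import scalar_polynomial_drift

        return scalar_polynomial_drift(net, v, c1=c1_request)

    Q, lin, const, c3, zeta_bar = _dd_constants(net, v)
    scale = max(1.0, float(np.max(np.abs(v))))
    q_nonpos = bool(np.all(Q <= _W_TOL * scale))
    notes = ""

    c1 = float(np.min(-lin / v))
    c2 = max(const, 0.0)
    dd1 = q_nonpos and c1 > 0
    if not dd1 and not q_nonpos:
        # negative definite quadratic: the drift maximum over the whole
        # space is finite for any c1 > 0
        Qs = (Q + Q.T) / 2.0
        lam_max = float(np.max(np.linalg.eigvalsh(Qs)))
        if lam_max < -_W_TOL * scale:
            c1 = float(c1_request) if (c1_request or 0) > 0 else 1.0
            s = lin + c1 * v
            c2 = max(const, 0.0) + max(
                0.0, 0.25 * float(s @ np.linalg.solve(-Qs, s)))
            dd1 = True
            notes = "dd1 via negative definite quadratic"
    if not dd1 and q_nonpos:
        # quadratic domination: coordinates whose linear part does not decay
        # must carry strictly negative Q diagonal
        diag = np.diag(Q)
        need = lin >= 0
        if np.all(diag[need] < -_W_TOL * scale):
            if c1_request is not None and c1_request > 0:
                c1 = float(c1_request)
            else:
                neg = lin < 0
                c1 = 1.0
                if np.any(neg):
                    c1 = min(1.0, 0.5 * float(np.min(-lin[neg] / v[neg])))
            c2 = max(const, 0.0)
            s = lin + c1 * v
            for i in range(net.d):
                if s[i] > 0:
                    if diag[i] < 0:
                        c2 += s[i] ** 2 / (-4.0 * diag[i])
                    else:  # pragma: no cover - excluded by `need` check
                        c1 = 0.0
                        break
            dd1 = c1 > 0
            if dd1:
                notes = "dd1 via quadratic domination"
    if not dd1:
        c1 = max(c1, 0.0)

    gamma = c2 / c1 if dd1 and c1 > 0 else math.inf
    return DDCertificate(
        v=v, c1=c1 if dd1 else 0.0, c2=c2, c3=c3, gamma=gamma,
        zeta_bar=zeta_bar,
        dd1_verified=dd1,
        dd2_verified=bool(math.isfinite(c3)),
        notes=notes,
    )


def audit_certificate(
    net: ReactionNetwork,
    cert: DDCertificate,
    n_states: int = 1000,
    max_count: int = 1000,
    seed: int = 0,
) -> dict:
    """Randomized soundness audit of a DD certificate.

    Samples lattice states and checks the DD1/DD2 inequalities against
    exact propensities (eval hints where available, suprema otherwise).
    Returns the worst slacks; nonnegative slacks mean no violation.
    """
    rng = np.random.default_rng(seed)
    v = cert.v
    d = net.d
    states = rng.integers(0, max_count + 1, size=(n_states, d))
    states[:min(5, n_states)] = 0  # include the origin region
    worst1 = math.inf
    worst2 = math.inf
    have_hints = all(
        r.propensity.kind == MASS_ACTION or r.propensity.eval_hint is not None
        for r in net.reactions
    )
    S = net.stoichiometry_matrix()
    for x in states:
        if have_hints:
            lam = evaluate_propensities(net, x)
        else:
            lam = _envelope_propensities(net, x)
        w = S.T @ v if net.K else np.zeros(0)
        drift = float(lam @ w)
        vx = float(v @ x)
        if cert.dd1_verified:
            worst1 = min(worst1, cert.c2 - cert.c1 * vx - drift)
        if cert.dd2_verified:
            diff = float(lam @ (w ** 2))
            worst2 = min(worst2, cert.c3 * (1.0 + vx) - diff)
    return {"dd1_worst_slack": worst1, "dd2_worst_slack": worst2,
            "n_states": n_states}


def _envelope_propensities(net: ReactionNetwork, x) -> np.ndarray:
    """Propensity upper envelope usable without eval hints."""
    x = np.asarray(x, dtype=float)
    lam = np.zeros(net.K)
    for k, r in enumerate(net.reactions):
        p = r.propensity
        if p.kind == MASS_ACTION:
            a = p.rate_constant
            for nm, m in p.reactant_multiset.items():
                a *= _falling(x[net.species_index(nm)], m)
            lam[k] = max(a, 0.0)
        elif p.kind == BOUNDED:
            lam[k] = p.sup_bound
        else:
            lam[k] = p.sup_bound * x[net.species_index(p.scale_species)]
    return lam
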