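"""Stochastic simulation (Gillespie direct method), deterministic
reaction-rate equations, and the divergence experiments.

The SSA layer validates certificates empirically: ensemble moments must
stay below certified bound tables, long-run time averages of ergodic
networks must match ensemble averages (the ergodic theorem), and
non-certifiable networks are probed for the diverging-moment /
exploding-trajectory signatures that certificates rightly refuse.

Mass-action networks run through numba kernels when available
(:mod:`ergokit._ssa_core`); networks with bounded-function propensities
fall back to a pure-Python direct method that evaluates their closed
forms (``eval_hint``).  Every path derives its seed from
``numpy.random.SeedSequence(master_seed)`` so ensembles are reproducible
and independent of scheduling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from . import _ssa_core as core
from . import fixtures as _fixtures
from .drift import evaluate_propensities, polynomial_propensities
from .network import MASS_ACTION, ReactionNetwork

__all__ = [
    "Trajectory",
    "EnsembleMoments",
    "RRESolution",
    "ssa",
    "ensemble_moments",
    "time_average",
    "rre",
    "drift_roots_1d",
    "divergence_experiment",
]

DEFAULT_MAX_EVENTS = 10_000_000
DEFAULT_PROP_CAP = 1e6

_STOP = {0: "horizon", 1: "absorbed", 2: "explosion_guard", 3: "explosion_guard"}


def _mass_action_arrays(net: ReactionNetwork):
    if any(r.propensity.kind != MASS_ACTION for r in net.reactions):
        return None
    K, d = net.K, net.d
    R = np.zeros((K, d), dtype=np.int64)
    Z = np.zeros((K, d), dtype=np.int64)
    rates = np.zeros(K)
    for k, r in enumerate(net.reactions):
        for nm, m in r.propensity.reactant_multiset.items():
            R[k, net.species_index(nm)] = m
        Z[k] = r.zeta
        rates[k] = r.propensity.rate_constant
    return R, Z, rates


def _path_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % np.uint32(2**31 - 1)


@dataclass
class Trajectory:
    """Piecewise-constant jump trajectory.

    ``states`` reconstructs the full path lazily from the reaction
    record; every increment is a stoichiometric column by construction.
    """

    x0: np.ndarray
    jump_times: np.ndarray
    reaction_indices: np.ndarray
    stopped_reason: str
    seed: int
    t_end: float
    t_stop: float
    network: ReactionNetwork

    @property
    def times(self) -> np.ndarray:
        return np.concatenate([[0.0], self.jump_times])

    @property
    def states(self) -> np.ndarray:
        Z = self.network.stoichiometry_matrix().T  # (K, d)
        if len(self.reaction_indices) == 0:
            return self.x0[None, :].astype(float)
        inc = np.cumsum(Z[self.reaction_indices], axis=0)
        return np.vstack([self.x0, self.x0 + inc]).astype(float)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def ssa(net: ReactionNetwork, x0, t_end: float, seed: int = 0,
        guard: dict | None = None) -> Trajectory:
    """One exact direct-method trajectory with explosion guards.

    ``guard`` may override ``max_events`` (default 1e7) and
    ``propensity_cap`` (default 1e6 total events per time unit --
    stopping once the exit rate exceeds the cap mirrors the standard
    practice of aborting exploding runs).
    """
    guard = guard or {}
    max_events = int(guard.get("max_events", DEFAULT_MAX_EVENTS))
    prop_cap = float(guard.get("propensity_cap", DEFAULT_PROP_CAP))
    x0 = np.asarray(x0, dtype=np.int64)
    arrays = _mass_action_arrays(net)
    if arrays is not None:
        R, Z, rates = arrays
        times, which, stop, t_stop = core.ssa_events(
            R, Z, rates, x0, float(t_end), int(seed) % 2**31, max_events, prop_cap)
    else:
        times, which, stop, t_stop = _ssa_events_py(
            net, x0, float(t_end), int(seed), max_events, prop_cap)
    if stop == 1:  # absorbed: the state persists to the horizon
        t_stop = float(t_end)
    return Trajectory(x0=x0, jump_times=np.asarray(times),
                      reaction_indices=np.asarray(which, dtype=int),
                      stopped_reason=_STOP[stop], seed=int(seed),
                      t_end=float(t_end), t_stop=float(t_stop), network=net)


def _ssa_events_py(net, x0, t_end, seed, max_events, prop_cap):
    rng = np.random.default_rng(seed)
    Z = net.stoichiometry_matrix().T
    x = x0.astype(float).copy()
    t = 0.0
    times, which = [], []
    while True:
        lam = evaluate_propensities(net, x)
        tot = float(lam.sum())
        if tot <= 0.0:
            return np.array(times), np.array(which, dtype=int), 1, t
        if tot > prop_cap:
            return np.array(times), np.array(which, dtype=int), 2, t
        t_next = t + rng.exponential(1.0 / tot)
        if t_next >= t_end:
            return np.array(times), np.array(which, dtype=int), 0, t_end
        k = int(rng.choice(len(lam), p=lam / tot))
        times.append(t_next)
        which.append(k)
        x += Z[k]
        t = t_next
        if len(times) >= max_events:
            return np.array(times), np.array(which, dtype=int), 3, t


def _ssa_grid_py(net, x0, grid, seed, max_events, prop_cap):
    rng = np.random.default_rng(seed)
    Z = net.stoichiometry_matrix().T
    x = x0.astype(float).copy()
    t = 0.0
    out = np.empty((len(grid), net.d))
    g = 0
    stop = 0
    n = 0
    while True:
        lam = evaluate_propensities(net, x)
        tot = float(lam.sum())
        if tot <= 0.0:
            stop = 1
            break
        if tot > prop_cap:
            stop = 2
            break
        t_next = t + rng.exponential(1.0 / tot)
        while g < len(grid) and grid[g] < t_next:
            out[g] = x
            g += 1
        if g >= len(grid):
            break
        x += Z[int(rng.choice(len(lam), p=lam / tot))]
        t = t_next
        n += 1
        if n >= max_events:
            stop = 3
            break
    while g < len(grid):
        out[g] = x
        g += 1
    return out, stop, t


@dataclass
class EnsembleMoments:
    """Grid-sampled ensemble with moment accessors.

    ``states`` has shape (n_paths, n_times, d).  Standard errors are
    sample-sd / sqrt(n_paths); paths stopped by a guard are flagged
    censored (their moments are still reported but should be read as
    lower bounds).
    """

    times: np.ndarray
    states: np.ndarray
    seeds: np.ndarray
    censored: np.ndarray  # per-path bool
    network: ReactionNetwork

    @property
    def n_paths(self) -> int:
        return self.states.shape[0]

    def mean(self) -> np.ndarray:
        return self.states.mean(axis=0)

    def se_mean(self) -> np.ndarray:
        return self.states.std(axis=0, ddof=1) / math.sqrt(self.n_paths)

    def raw_moment(self, n: int) -> np.ndarray:
        return (self.states ** n).mean(axis=0)

    def weighted_moment(self, v, n: int = 1):
        """(moment, SE) of ``<v, X(t)>^n`` on the grid."""
        w = np.tensordot(self.states, np.asarray(v, dtype=float), axes=(2, 0)) ** n
        return w.mean(axis=0), w.std(axis=0, ddof=1) / math.sqrt(self.n_paths)


def ensemble_moments(net: ReactionNetwork, x0, n_paths: int, times,
                     seed: int = 0, guard: dict | None = None) -> EnsembleMoments:
    """Independent seeded SSA paths sampled on a common time grid."""
    if n_paths < 2:
        raise ValueError("need at least 2 paths for standard errors")
    guard = guard or {}
    max_events = int(guard.get("max_events", DEFAULT_MAX_EVENTS))
    prop_cap = float(guard.get("propensity_cap", DEFAULT_PROP_CAP))
    times = np.asarray(times, dtype=float)
    x0 = np.asarray(x0, dtype=np.int64)
    seeds = _path_seeds(seed, n_paths)
    states = np.empty((n_paths, len(times), net.d))
    censored = np.zeros(n_paths, dtype=bool)
    arrays = _mass_action_arrays(net)
    for p in range(n_paths):
        if arrays is not None:
            R, Z, rates = arrays
            out, stop, _ = core.ssa_grid(R, Z, rates, x0, times,
                                         int(seeds[p]), max_events, prop_cap)
        else:
            out, stop, _ = _ssa_grid_py(net, x0, times, int(seeds[p]),
                                        max_events, prop_cap)
        states[p] = out
        censored[p] = stop in (2, 3)
    return EnsembleMoments(times=times, states=states, seeds=seeds,
                           censored=censored, network=net)


def time_average(traj: Trajectory, f=None):
    """Time-weighted average ``(1/t) * integral f(X(s)) ds`` (ergodic
    theorem estimator).  ``f`` maps a state row to a scalar or vector;
    identity by default."""
    T = traj.t_stop
    if T <= 0:
        raise ValueError("trajectory has zero duration")
    st = traj.states
    times = np.concatenate([traj.times, [T]])
    dt = np.diff(times)
    vals = st if f is None else np.asarray([f(row) for row in st])
    return np.tensordot(dt, vals, axes=(0, 0)) / T


def stationary_time_average(net: ReactionNetwork, x0, t_burn: float,
                            t_end: float, seed: int = 0,
                            guard: dict | None = None):
    """Occupation-time first and second moments over ``[t_burn, t_end]``,
    computed in a streaming pass (no stored trajectory).  Returns
    ``(avg_x, avg_x2, stopped_reason)``."""
    guard = guard or {}
    max_events = int(guard.get("max_events", 2**62))
    prop_cap = float(guard.get("propensity_cap", DEFAULT_PROP_CAP))
    arrays = _mass_action_arrays(net)
    x0 = np.asarray(x0, dtype=np.int64)
    if arrays is None:
        raise ValueError("streaming time averages require mass-action kinetics")
    R, Z, rates = arrays
    a1, a2, stop, _ = core.ssa_time_average(
        R, Z, rates, x0, float(t_burn), float(t_end),
        int(seed) % 2**31, max_events, prop_cap)
    return a1, a2, _STOP[stop]


# ---------------------------------------------------------------------------
# deterministic layer
# ---------------------------------------------------------------------------

@dataclass
class RRESolution:
    times: np.ndarray
    states: np.ndarray            # (n_times, d)
    equilibrium: np.ndarray | None
    jacobian_eigs: np.ndarray | None
    converged: bool
    escape_time: float | None = None


def _rre_rhs(net):
    S = net.stoichiometry_matrix().astype(float)

    def rhs(t, y):
        return S @ polynomial_propensities(net, np.maximum(y, 0.0),
                                           convention="deterministic")

    return rhs


def rre(net: ReactionNetwork, x0, t_end: float, t_eval=None) -> RRESolution:
    """Integrate the reaction-rate equations (deterministic monomial
    convention) and characterize the terminal equilibrium.

    Finite-time blow-up is reported through ``escape_time``.
    """
    rhs = _rre_rhs(net)
    y0 = np.asarray(x0, dtype=float)

    def too_big(t, y):
        return float(np.max(np.abs(y)) - 1e9)
    too_big.terminal = True
    too_big.direction = 1.0

    sol = solve_ivp(rhs, (0.0, float(t_end)), y0, method="LSODA",
                    t_eval=t_eval, events=too_big, rtol=1e-9, atol=1e-9)
    if sol.t_events[0].size:
        return RRESolution(times=sol.t, states=sol.y.T, equilibrium=None,
                           jacobian_eigs=None, converged=False,
                           escape_time=float(sol.t_events[0][0]))
    y_end = sol.y[:, -1]
    y_eq = np.asarray(fsolve(lambda y: rhs(0.0, y), y_end), dtype=float)
    d = net.d
    J = np.zeros((d, d))
    h = 1e-6 * np.maximum(1.0, np.abs(y_eq))
    f0 = rhs(0.0, y_eq)
    for j in range(d):
        yp = y_eq.copy()
        yp[j] += h[j]
        J[:, j] = (rhs(0.0, yp) - f0) / h[j]
    eigs = np.linalg.eigvals(J)
    converged = bool(np.linalg.norm(y_end - y_eq) <= 1e-6 * (1 + np.linalg.norm(y_eq)))
    return RRESolution(times=sol.t, states=sol.y.T, equilibrium=y_eq,
                       jacobian_eigs=eigs, converged=converged)


# ---------------------------------------------------------------------------
# scalar drift roots
# ---------------------------------------------------------------------------

def scalar_drift_coefficients(net: ReactionNetwork, v=1.0,
                              convention: str = "stochastic") -> np.ndarray:
    """Coefficients (ascending) of the weighted drift polynomial of a
    single-species mass-action network."""
    if net.d != 1:
        raise ValueError("scalar drift requires a single species")
    v1 = float(np.asarray(v).ravel()[0])
    coeffs = np.zeros(5)
    for r in net.reactions:
        p = r.propensity
        if p.kind != MASS_ACTION:
            raise ValueError("scalar drift requires mass-action kinetics")
        w = v1 * float(r.zeta[0])
        m = p.order
        if convention == "deterministic":
            poly = np.zeros(m + 1)
            poly[m] = 1.0 / math.factorial(m)
        else:
            poly = {0: [1.0], 1: [0.0, 1.0], 2: [0.0, -0.5, 0.5],
                    3: [0.0, 1 / 3, -0.5, 1 / 6]}[m]
        contrib = p.rate_constant * w * np.asarray(poly)
        coeffs[: len(contrib)] += contrib
    deg = int(np.max(np.nonzero(np.abs(coeffs) > 0)[0])) if np.any(coeffs) else 0
    return coeffs[: deg + 1]


def drift_roots_1d(net: ReactionNetwork, v=1.0,
                   convention: str = "stochastic") -> dict:
    """Sorted real roots of the scalar drift polynomial and the sign of
    the drift beyond the largest root (a positive sign marks the escape
    region of a bistable well)."""
    coeffs = scalar_drift_coefficients(net, v, convention)
    roots = np.polynomial.polynomial.polyroots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    sign_beyond = 0.0
    if len(real):
        x_test = real[-1] + 1.0 + abs(real[-1]) * 0.1
        sign_beyond = float(np.sign(
            np.polynomial.polynomial.polyval(x_test, coeffs)))
    return {"roots": real, "coefficients": coeffs,
            "positive_drift_beyond_largest_root": sign_beyond > 0}


# ---------------------------------------------------------------------------
# divergence experiments
# ---------------------------------------------------------------------------

def divergence_experiment(name: str, params: dict | None = None,
                          n_runs: int = 1000, t_end: float = 100.0,
                          seed: int = 0, guard: dict | None = None) -> dict:
    """Reproducible stochastic-instability probes.

    ``well_jumping``: count guarded SSA runs stopped before the horizon
    (escape over the deterministic separatrix followed by explosion).
    ``unstable_pair``: ratio of the ensemble first moment of the driven
    species at ``t_end`` versus ``t_end / 2`` (a ratio significantly
    above 1 is the diverging-moment signature).
    """
    if name == "well_jumping":
        net = _fixtures.build_fixture("well_jumping_22", params)
    elif name == "unstable_pair":
        net = _fixtures.build_fixture("unstable_pair_26", params)
    else:
        raise ValueError("name must be 'well_jumping' or 'unstable_pair'")
    x0 = _fixtures.default_initial_state(net)
    grid = np.array([t_end / 2.0, t_end])
    ens = ensemble_moments(net, x0, n_runs, grid, seed=seed, guard=guard)
    n_stopped = int(ens.censored.sum())
    out = {"n_runs": n_runs, "n_stopped": n_stopped,
           "fraction_stopped": n_stopped / n_runs}
    if name == "unstable_pair":
        i2 = net.species_index("X2")
        m = ens.mean()[:, i2]
        se = ens.se_mean()[:, i2]
        out.update({
            "m_half": float(m[0]), "m_end": float(m[1]),
            "se_half": float(se[0]), "se_end": float(se[1]),
            "moment_growth_ratio": float(m[1] / m[0]) if m[0] > 0 else math.inf,
        })
    return out
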