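"""Numba-accelerated SSA kernels for pure mass-action networks.

All kernels implement Gillespie's direct method with the stochastic
falling-factorial propensity convention and two explosion guards: a cap
on the number of events and a cap on the total propensity (when the
total exit rate exceeds the cap the process is effectively exploding and
the run is stopped, mirroring the usual simulation practice for
non-ergodic networks).

Stop codes: 0 = horizon reached, 1 = absorbed (all propensities zero),
2 = propensity cap, 3 = event cap.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _propensities(R, rates, x, lam):
    K, d = R.shape
    tot = 0.0
    for k in range(K):
        a = rates[k]
        for i in range(d):
            m = R[k, i]
            if m == 1:
                a *= x[i]
            elif m == 2:
                a *= x[i] * (x[i] - 1.0) * 0.5
            elif m == 3:
                a *= x[i] * (x[i] - 1.0) * (x[i] - 2.0) / 6.0
        if a < 0.0:
            a = 0.0
        lam[k] = a
        tot += a
    return tot


@njit(cache=True)
def ssa_events(R, Z, rates, x0, t_end, seed, max_events, prop_cap):
    """Full event record: (times, reaction indices, stop_code, t_stop)."""
    np.random.seed(seed)
    K, d = R.shape
    x = x0.astype(np.float64)
    lam = np.zeros(K)
    cap = 65536
    times = np.empty(cap)
    which = np.empty(cap, dtype=np.int32)
    n = 0
    t = 0.0
    stop = 0
    while True:
        tot = _propensities(R, rates, x, lam)
        if tot <= 0.0:
            stop = 1
            break
        if tot > prop_cap:
            stop = 2
            break
        t_next = t + np.random.exponential(1.0 / tot)
        if t_next >= t_end:
            t = t_end
            stop = 0
            break
        u = np.random.random() * tot
        s = 0.0
        k_sel = K - 1
        for k in range(K):
            s += lam[k]
            if u <= s:
                k_sel = k
                break
        if n >= cap:
            cap *= 2
            new_t = np.empty(cap)
            new_w = np.empty(cap, dtype=np.int32)
            new_t[:n] = times
            new_w[:n] = which
            times = new_t
            which = new_w
        times[n] = t_next
        which[n] = k_sel
        n += 1
        for i in range(d):
            x[i] += Z[k_sel, i]
        t = t_next
        if n >= max_events:
            stop = 3
            break
    return times[:n].copy(), which[:n].copy(), stop, t


@njit(cache=True)
def ssa_grid(R, Z, rates, x0, grid, seed, max_events, prop_cap):
    """States sampled on a time grid: (states, stop_code, t_stop).

    After an early stop the remaining grid points repeat the last state
    (callers should treat guard-stopped paths as censored).
    """
    np.random.seed(seed)
    K, d = R.shape
    x = x0.astype(np.float64)
    lam = np.zeros(K)
    n_grid = grid.shape[0]
    out = np.empty((n_grid, d))
    g = 0
    t = 0.0
    stop = 0
    n = 0
    t_end = grid[n_grid - 1]
    while True:
        tot = _propensities(R, rates, x, lam)
        if tot <= 0.0:
            stop = 1
            break
        if tot > prop_cap:
            stop = 2
            break
        t_next = t + np.random.exponential(1.0 / tot)
        while g < n_grid and grid[g] < t_next:
            out[g] = x
            g += 1
        if g >= n_grid:
            break
        u = np.random.random() * tot
        s = 0.0
        k_sel = K - 1
        for k in range(K):
            s += lam[k]
            if u <= s:
                k_sel = k
                break
        for i in range(d):
            x[i] += Z[k_sel, i]
        t = t_next
        n += 1
        if n >= max_events:
            stop = 3
            break
    while g < n_grid:
        out[g] = x
        g += 1
    return out, stop, t


@njit(cache=True)
def ssa_time_average(R, Z, rates, x0, t_burn, t_end, seed, max_events, prop_cap):
    """Occupation-time averages of x and x^2 over [t_burn, t_end]."""
    np.random.seed(seed)
    K, d = R.shape
    x = x0.astype(np.float64)
    lam = np.zeros(K)
    acc1 = np.zeros(d)
    acc2 = np.zeros(d)
    t = 0.0
    stop = 0
    n = 0
    while True:
        tot = _propensities(R, rates, x, lam)
        if tot <= 0.0:
            lo = t if t > t_burn else t_burn
            if t_end > lo:
                acc1 += x * (t_end - lo)
                acc2 += x * x * (t_end - lo)
            stop = 1
            t = t_end
            break
        if tot > prop_cap:
            stop = 2
            break
        t_next = t + np.random.exponential(1.0 / tot)
        lo = t if t > t_burn else t_burn
        hi = t_next if t_next < t_end else t_end
        if hi > lo:
            acc1 += x * (hi - lo)
            acc2 += x * x * (hi - lo)
        if t_next >= t_end:
            t = t_end
            break
        u = np.random.random() * tot
        s = 0.0
        k_sel = K - 1
        for k in range(K):
            s += lam[k]
            if u <= s:
                k_sel = k
                break
        for i in range(d):
            x[i] += Z[k_sel, i]
        t = t_next
        n += 1
        if n >= max_events:
            stop = 3
            break
    span = (t if t < t_end else t_end) - t_burn
    if span <= 0.0:
        span = 1.0
        stop = max(stop, 2)
    return acc1 / span, acc2 / span, stop, t
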