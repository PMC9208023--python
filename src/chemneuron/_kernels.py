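"""Direct-method SSA kernel over compiled reaction arrays.

The kernel simulates exact mass-action kinetics between scheduled injection
times.  At each injection the pending reaction time is discarded and redrawn;
because exponential waiting times are memoryless this preserves exactness.
Recording is sample-and-hold on a fixed grid: the state reported at a grid
time equals the state immediately after any injection at that instant.

A numba-compiled and a pure-Python version of the same algorithm are
provided; both are deterministic given the seed (they need not agree with
each other draw-for-draw).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def _ssa_core(x0, rate, r1, r2, same, stoich,
              hill_src, hill_m, hill_theta, hill_scale,
              ev_time, ev_sp, ev_size, grid, seed):
    np.random.seed(seed)
    n_r = rate.shape[0]
    n_g = grid.shape[0]
    n_e = ev_time.shape[0]
    horizon = grid[n_g - 1]
    x = x0.copy()
    out = np.zeros((n_g, x0.shape[0]), dtype=np.int64)
    a = np.zeros(n_r)
    t = 0.0
    gi = 0
    ei = 0
    # apply any injections scheduled at t = 0
    while ei < n_e and ev_time[ei] <= 0.0:
        x[ev_sp[ei]] += ev_size[ei]
        ei += 1
    while True:
        # propensities
        a0 = 0.0
        for k in range(n_r):
            v = rate[k]
            i1 = r1[k]
            if i1 >= 0:
                if same[k]:
                    v *= x[i1] * (x[i1] - 1) * 0.5
                else:
                    v *= x[i1]
                    i2 = r2[k]
                    if i2 >= 0:
                        v *= x[i2]
            h = hill_src[k]
            if h >= 0:
                b = x[h]
                if b > 0:
                    # ratio form is overflow-safe for steep exponents
                    v *= hill_scale[k] / (1.0 + (hill_theta[k] / b) ** hill_m[k])
                else:
                    v = 0.0
            a[k] = v
            a0 += v
        if a0 > 0.0:
            tau = -np.log(np.random.random()) / a0
        else:
            tau = np.inf
        boundary = horizon
        if ei < n_e and ev_time[ei] < boundary:
            boundary = ev_time[ei]
        if t + tau < boundary:
            t_new = t + tau
            while gi < n_g and grid[gi] < t_new:
                out[gi] = x
                gi += 1
            # choose reaction
            u = np.random.random() * a0
            acc = 0.0
            chosen = n_r - 1
            for k in range(n_r):
                acc += a[k]
                if u < acc:
                    chosen = k
                    break
            x += stoich[chosen]
            t = t_new
        else:
            while gi < n_g and grid[gi] < boundary:
                out[gi] = x
                gi += 1
            t = boundary
            if boundary >= horizon:
                # grid points at the horizon report the state after any
                # injection scheduled exactly there
                while ei < n_e and ev_time[ei] <= horizon:
                    x[ev_sp[ei]] += ev_size[ei]
                    ei += 1
                while gi < n_g:
                    out[gi] = x
                    gi += 1
                break
            while ei < n_e and ev_time[ei] <= t:
                x[ev_sp[ei]] += ev_size[ei]
                ei += 1
    return out


if HAVE_NUMBA:
    _ssa_core_numba = numba.njit(cache=True, fastmath=False)(_ssa_core)
else:  # pragma: no cover
    _ssa_core_numba = None


def run_ssa(x0, rate, r1, r2, same, stoich,
            hill_src, hill_m, hill_theta, hill_scale,
            ev_time, ev_sp, ev_size, grid, seed, use_numba=True):
    args = (x0, rate, r1, r2, same, stoich,
            hill_src, hill_m, hill_theta, hill_scale,
            ev_time, ev_sp, ev_size, grid, seed)
    if use_numba and HAVE_NUMBA:
        return _ssa_core_numba(*args)
    return _ssa_core(*args)
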