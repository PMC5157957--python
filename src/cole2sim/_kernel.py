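"""Numba core of the direct-method Gillespie simulator.

Mass-action propensities over at most two reactant slots per reaction
(order 2 in one slot means an identical pair, contributing x(x-1)/2).
Piecewise-constant time dependence is handled exactly: a waiting time that
would cross a schedule breakpoint is capped at the breakpoint and redrawn,
which is statistically exact because propensities are constant in between.

The legacy MT19937 generator is used (np.random.seed / np.random.random
inside the jitted function), so a (system, initial, seed) triple fixes the
event sequence bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ssa_run_grid(stoich, r_spec, r_ord, rates, scheduled,
                 bp_times, bp_vals, x0, t_grid, seed):
    """One SSA realization, sampled onto ``t_grid`` by last-value-carried-forward.

    Returns ``(out, n_events, x_final)`` where ``out`` has shape
    ``(n_species, n_grid)``.  ``n_events == -1`` signals a non-finite
    propensity sum (caller raises with context).
    """
    np.random.seed(seed)
    n_r = rates.shape[0]
    n_s = x0.shape[0]
    n_t = t_grid.shape[0]
    n_bp = bp_times.shape[0]
    out = np.empty((n_s, n_t), dtype=np.int64)
    x = x0.copy()
    t = t_grid[0]
    t_end = t_grid[n_t - 1]
    ib = 0
    while ib < n_bp and bp_times[ib] <= t:
        ib += 1
    factor = bp_vals[ib - 1] if ib > 0 else 1.0
    kg = 0
    n_events = 0
    a = np.empty(n_r)
    while True:
        a0 = 0.0
        for r in range(n_r):
            pr = rates[r]
            if scheduled[r]:
                pr *= factor
            if pr > 0.0:
                for q in range(2):
                    si = r_spec[r, q]
                    if si >= 0:
                        xi = x[si]
                        if r_ord[r, q] == 1:
                            pr *= xi
                        else:
                            pr *= xi * (xi - 1) * 0.5
            if pr > 0.0:
                a[r] = pr
                a0 += pr
            else:
                a[r] = 0.0
        if not np.isfinite(a0):
            return out, -1, x
        t_bp = bp_times[ib] if ib < n_bp else np.inf
        if a0 <= 0.0:
            t_next = np.inf
        else:
            u1 = np.random.random()
            while u1 <= 0.0:
                u1 = np.random.random()
            t_next = t - np.log(u1) / a0
        if t_bp <= t_end and t_next >= t_bp:
            # cap at the breakpoint, update the factor, redraw
            while kg < n_t and t_grid[kg] < t_bp:
                for si in range(n_s):
                    out[si, kg] = x[si]
                kg += 1
            t = t_bp
            factor = bp_vals[ib]
            ib += 1
            continue
        if t_next > t_end:
            while kg < n_t:
                for si in range(n_s):
                    out[si, kg] = x[si]
                kg += 1
            return out, n_events, x
        while kg < n_t and t_grid[kg] < t_next:
            for si in range(n_s):
                out[si, kg] = x[si]
            kg += 1
        u2 = np.random.random() * a0
        c = 0.0
        r_sel = n_r - 1
        for r in range(n_r):
            c += a[r]
            if u2 < c:
                r_sel = r
                break
        for si in range(n_s):
            x[si] += stoich[r_sel, si]
        t = t_next
        n_events += 1
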