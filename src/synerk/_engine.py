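"""Numba kernels for the exact SSA and the adaptive tau-leap propagator.

State is an integer molecule-count vector.  Reversible reactions arrive here
already split into directed channels.  Propensities use the standard
count-space combinatorics (n for unimolecular, n1*n2 for heterodimeric,
n*(n-1)/2 for homodimeric channels); the conversion from concentration-space
rate constants happens in :mod:`synerk.simulate`.

Clamped species (stimulus inputs held at a target level) are reset to their
clamp value after every state update, which realises an ideal buffered
source: reactions read the clamped count but cannot deplete it.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _propensities(n, c, r1, r2, dbl, a):
    for j in range(c.size):
        i1 = r1[j]
        if i1 < 0:
            a[j] = c[j]
        elif dbl[j]:
            a[j] = c[j] * n[i1] * (n[i1] - 1) * 0.5
        else:
            aj = c[j] * n[i1]
            i2 = r2[j]
            if i2 >= 0:
                aj *= n[i2]
            a[j] = aj


@njit(cache=True, inline="always")
def _apply_clamps(n, clamp_idx, clamp_val):
    for k in range(clamp_idx.size):
        n[clamp_idx[k]] = clamp_val[k]


@njit(cache=True)
def ssa_segment(n, t, t_end, c, r1, r2, dbl, stoich, clamp_idx, clamp_val,
                grid, gpos, out):
    """Exact SSA from t to t_end; records states at grid points in [t, t_end).

    Returns (t_end, gpos).  ``out`` rows are filled for every grid index
    g with t <= grid[g] < t_end.
    """
    n_rx = c.size
    a = np.empty(n_rx)
    _apply_clamps(n, clamp_idx, clamp_val)
    while t < t_end:
        _propensities(n, c, r1, r2, dbl, a)
        a0 = 0.0
        for j in range(n_rx):
            a0 += a[j]
        if a0 <= 0.0:
            t_next = t_end
        else:
            t_next = t - np.log(np.random.random()) / a0
        horizon = t_next if t_next < t_end else t_end
        while gpos < grid.size and grid[gpos] < horizon:
            for i in range(n.size):
                out[gpos, i] = n[i]
            gpos += 1
        if t_next >= t_end:
            break
        # choose channel
        u = np.random.random() * a0
        acc = 0.0
        j_fire = n_rx - 1
        for j in range(n_rx):
            acc += a[j]
            if u < acc:
                j_fire = j
                break
        for i in range(n.size):
            n[i] += stoich[j_fire, i]
        _apply_clamps(n, clamp_idx, clamp_val)
        t = t_next
    return t_end, gpos


@njit(cache=True)
def _ssa_steps(n, t, t_end, c, r1, r2, dbl, stoich, clamp_idx, clamp_val,
               grid, gpos, out, max_steps):
    """Up to max_steps exact events; helper for the tau-leap small-count path."""
    n_rx = c.size
    a = np.empty(n_rx)
    steps = 0
    while t < t_end and steps < max_steps:
        _propensities(n, c, r1, r2, dbl, a)
        a0 = 0.0
        for j in range(n_rx):
            a0 += a[j]
        if a0 <= 0.0:
            t_next = t_end
        else:
            t_next = t - np.log(np.random.random()) / a0
        horizon = t_next if t_next < t_end else t_end
        while gpos < grid.size and grid[gpos] < horizon:
            for i in range(n.size):
                out[gpos, i] = n[i]
            gpos += 1
        if t_next >= t_end:
            t = t_end
            break
        u = np.random.random() * a0
        acc = 0.0
        j_fire = n_rx - 1
        for j in range(n_rx):
            acc += a[j]
            if u < acc:
                j_fire = j
                break
        for i in range(n.size):
            n[i] += stoich[j_fire, i]
        _apply_clamps(n, clamp_idx, clamp_val)
        t = t_next
        steps += 1
    return t, gpos


@njit(cache=True)
def tau_segment(n, t, t_end, c, r1, r2, dbl, stoich, clamp_idx, clamp_val,
                grid, gpos, out, eps):
    """Adaptive tau-leap (propensity change bounded by eps per leap).

    Channels whose reactant populations are small (< 10 firings from
    exhaustion) are treated as critical and simulated exactly; when the
    selected leap would be shorter than a few exact events, the kernel
    falls back to exact SSA steps for a window.  Candidate leaps driving
    any population negative are rejected and retried at half the leap.
    """
    n_rx = c.size
    n_sp = n.size
    a = np.empty(n_rx)
    critical = np.empty(n_rx, np.bool_)
    mu = np.empty(n_sp)
    sig2 = np.empty(n_sp)
    k_fire = np.empty(n_rx, np.int64)
    trial = np.empty(n_sp, np.int64)
    _apply_clamps(n, clamp_idx, clamp_val)
    while t < t_end:
        _propensities(n, c, r1, r2, dbl, a)
        a0 = 0.0
        for j in range(n_rx):
            a0 += a[j]
        if a0 <= 0.0:
            while gpos < grid.size and grid[gpos] < t_end:
                for i in range(n_sp):
                    out[gpos, i] = n[i]
                gpos += 1
            t = t_end
            break
        # classify critical channels
        a0_crit = 0.0
        for j in range(n_rx):
            crit = False
            if a[j] > 0.0:
                for i in range(n_sp):
                    v = stoich[j, i]
                    if v < 0 and n[i] < 10 * (-v):
                        crit = True
                        break
            critical[j] = crit
            if crit:
                a0_crit += a[j]
        # leap length from non-critical channels (Cao/Gillespie/Petzold)
        for i in range(n_sp):
            mu[i] = 0.0
            sig2[i] = 0.0
        any_noncrit = False
        for j in range(n_rx):
            if critical[j] or a[j] <= 0.0:
                continue
            any_noncrit = True
            for i in range(n_sp):
                v = stoich[j, i]
                if v != 0:
                    mu[i] += v * a[j]
                    sig2[i] += v * v * a[j]
        tau = t_end - t
        if any_noncrit:
            for i in range(n_sp):
                if mu[i] == 0.0 and sig2[i] == 0.0:
                    continue
                # reaction order of the fastest consumer of species i
                g = 1.0
                for j in range(n_rx):
                    if a[j] > 0.0 and not critical[j]:
                        if r1[j] == i or r2[j] == i:
                            order = 1.0
                            if r2[j] >= 0:
                                order = 2.0
                            if dbl[j] and n[i] > 1:
                                order = 2.0 + 1.0 / (n[i] - 1)
                            if order > g:
                                g = order
                bound = eps * n[i] / g
                if bound < 1.0:
                    bound = 1.0
                if mu[i] != 0.0:
                    cand = bound / abs(mu[i])
                    if cand < tau:
                        tau = cand
                if sig2[i] > 0.0:
                    cand = bound * bound / sig2[i]
                    if cand < tau:
                        tau = cand
        else:
            tau = 0.0  # everything critical -> exact steps
        if tau < 10.0 / a0:
            t, gpos = _ssa_steps(n, t, t_end, c, r1, r2, dbl, stoich,
                                 clamp_idx, clamp_val, grid, gpos, out, 100)
            continue
        # time to next critical event
        tau2 = np.inf
        if a0_crit > 0.0:
            tau2 = -np.log(np.random.random()) / a0_crit
        fire_critical = tau2 <= tau and tau2 <= t_end - t
        leap = tau if tau < tau2 else tau2
        if leap > t_end - t:
            leap = t_end - t
            fire_critical = False
        # draw firings, retrying at half the leap on negative excursions
        accepted = False
        while not accepted:
            for j in range(n_rx):
                if critical[j] or a[j] <= 0.0:
                    k_fire[j] = 0
                else:
                    k_fire[j] = np.random.poisson(a[j] * leap)
            if fire_critical:
                u = np.random.random() * a0_crit
                acc = 0.0
                for j in range(n_rx):
                    if critical[j]:
                        acc += a[j]
                        if u < acc:
                            k_fire[j] += 1
                            break
            for i in range(n_sp):
                trial[i] = n[i]
            ok = True
            for j in range(n_rx):
                if k_fire[j] > 0:
                    for i in range(n_sp):
                        trial[i] += k_fire[j] * stoich[j, i]
            for i in range(n_sp):
                if trial[i] < 0:
                    ok = False
                    break
            if ok:
                accepted = True
            else:
                leap *= 0.5
                fire_critical = False
                if leap * a0 < 1.0:
                    # give up on leaping here; take exact steps instead
                    t, gpos = _ssa_steps(n, t, t_end, c, r1, r2, dbl, stoich,
                                         clamp_idx, clamp_val, grid, gpos,
                                         out, 100)
                    break
        if not accepted:
            continue
        horizon = t + leap
        if horizon > t_end:
            horizon = t_end
        while gpos < grid.size and grid[gpos] < horizon:
            for i in range(n_sp):
                out[gpos, i] = n[i]
            gpos += 1
        for i in range(n_sp):
            n[i] = trial[i]
        _apply_clamps(n, clamp_idx, clamp_val)
        t = t + leap
    return t_end, gpos
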