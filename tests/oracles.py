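"""Independent reference implementations used only by the tests.

The explicit-subunit chain enumerates all 2^4 closed/activated subunit
combinations plus the open state (17 states, no aggregation); it is a
brute-force oracle for the aggregated 9-state model.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from kvgating.constants import DEFAULT_CONSTANTS
from kvgating.kinetics import rate_alpha, rate_beta


def explicit_states():
    """16 subunit combinations (s1, s2, s3, s4) plus the open state."""
    states = [(a, b, c, d) for a in (0, 1) for b in (0, 1)
              for c in (0, 1) for d in (0, 1)]
    return states + ["O"]


def explicit_generator(asm, V, pc=DEFAULT_CONSTANTS):
    states = explicit_states()
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    ac, bc = rate_alpha(asm.common, V, pc), rate_beta(asm.common, V, pc)
    ad, bd = rate_alpha(asm.distinct, V, pc), rate_beta(asm.distinct, V, pc)
    for s in states[:-1]:
        i = idx[s]
        for pos in range(4):
            flipped = list(s)
            flipped[pos] = 1 - flipped[pos]
            j = idx[tuple(flipped)]
            fwd, bwd = (ac, bc) if pos < 3 else (ad, bd)
            Q[i, j] = fwd if s[pos] == 0 else bwd
    i = idx[(1, 1, 1, 1)]
    Q[i, idx["O"]] = asm.opening_rate
    Q[idx["O"], i] = asm.closing_rate
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return Q


def aggregate(p_explicit):
    """Map explicit occupancies onto the 9 aggregated classes,
    ordered (n ascending, distinct C before A, open last)."""
    states = explicit_states()
    out = np.zeros(p_explicit.shape[:-1] + (9,))
    for i, s in enumerate(states):
        if s == "O":
            out[..., 8] += p_explicit[..., i]
        else:
            n = s[0] + s[1] + s[2]
            out[..., 2 * n + s[3]] += p_explicit[..., i]
    return out


def explicit_equilibrium(asm, V, pc=DEFAULT_CONSTANTS):
    Q = explicit_generator(asm, V, pc)
    # long-time propagation from uniform start; rates are O(1/ms)
    p = np.full(Q.shape[0], 1.0 / Q.shape[0])
    return p @ expm(Q * 1e5)


def explicit_propagate(asm, segments, holding, t_grid, pc=DEFAULT_CONSTANTS):
    """Propagate the 17-state chain over piecewise-constant segments."""
    p = explicit_equilibrium(asm, holding, pc)
    out = np.empty((len(t_grid), len(p)))
    out[0] = p
    start = 0.0
    for dur, volt in segments:
        Q = explicit_generator(asm, volt, pc)
        mask = (t_grid > start + 1e-12) & (t_grid <= start + dur + 1e-12)
        for k in np.nonzero(mask)[0]:
            out[k] = p @ expm(Q * (t_grid[k] - start))
        p = p @ expm(Q * dur)
        start += dur
    return out


def ode_propagate(asm9_generator_fn, segments, p0, t_grid):
    """Stiff-ODE reference for the 9-state master equation.

    asm9_generator_fn(V) must return the 9x9 generator; the solution is
    integrated segment by segment with LSODA at tight tolerances.
    """
    p = np.array(p0, dtype=float)
    out = np.empty((len(t_grid), len(p0)))
    out[0] = p
    start = 0.0
    for dur, volt in segments:
        Q = asm9_generator_fn(volt)
        mask = (t_grid > start + 1e-12) & (t_grid <= start + dur + 1e-12)
        times = t_grid[mask]
        if len(times):
            sol = solve_ivp(lambda t, y: y @ Q, (start, times[-1]), p,
                            t_eval=times, method="LSODA",
                            rtol=1e-11, atol=1e-13)
            out[np.nonzero(mask)[0]] = sol.y.T
            p = sol.y[:, -1]
        start += dur
    return out
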