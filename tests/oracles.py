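"""Independent brute-force oracles for the phase model tests.

These deliberately share no code with the sampler: posteriors are computed by
dense grid integration (dynamic programming over the ordering chain), so they
can certify the MCMC output.
"""

import numpy as np


def two_phase_marginals(r1, s1, r2, s2, window, m=240):
    """Exact (grid-integrated) theta marginals of the 2-phase, 2-date model.

    Identity calibration curve with no curve error. Chain of constraints:

        W_old >= a1 >= th1 >= b1 >= a2 >= th2 >= b2 >= W_young

    with joint density N(r1; th1, s1) N(r2; th2, s2) / ((a1-b1)(a2-b2)) and
    flat boundary priors. All six parameters are discretised on an m-point
    grid and the boundary parameters are summed out by cumulative sums:

        A(th1, b1)  = sum_{a1 >= th1} 1/(a1 - b1)          (suffix over a1)
        M(th1, a2)  = sum_{b1 in [a2, th1]} A(th1, b1)     (prefix over b1)
        C(a2, th2)  = sum_{b2 <= th2} 1/(a2 - b2)          (prefix over b2)
        J(th1, th2) = L1(th1) [M C](th1, th2) L2(th2)

    Returns (grid ascending, P(th1), P(th2)) as probability masses.
    """
    wo, wy = window
    g = np.linspace(wy, wo, m)
    idx = np.arange(m)
    diff = g[:, None] - g[None, :]
    inv = np.where(diff > 0, 1.0 / np.where(diff > 0, diff, 1.0), 0.0)
    A = np.cumsum(inv[::-1, :], axis=0)[::-1, :]
    C = np.cumsum(inv, axis=1)
    pre = np.cumsum(np.where(idx[None, :] <= idx[:, None], A, 0.0), axis=1)
    tot = pre[idx, idx][:, None]
    prev = np.concatenate([np.zeros((m, 1)), pre[:, :-1]], axis=1)
    M = np.where(idx[None, :] <= idx[:, None], tot - prev, 0.0)
    Cm = np.where(idx[:, None] >= idx[None, :], C, 0.0)
    J = M @ Cm
    L1 = np.exp(-0.5 * (r1 - g) ** 2 / s1**2)
    L2 = np.exp(-0.5 * (r2 - g) ** 2 / s2**2)
    J = L1[:, None] * J * L2[None, :]
    J = np.where(idx[:, None] >= idx[None, :], J, 0.0)
    Z = J.sum()
    return g, J.sum(axis=1) / Z, J.sum(axis=0) / Z


def total_variation(draws, grid, mass):
    """TV distance between MCMC draws (binned onto grid cells) and a mass."""
    step = grid[1] - grid[0]
    edges = np.concatenate((grid - step / 2, [grid[-1] + step / 2]))
    h, _ = np.histogram(draws, bins=edges)
    h = h / h.sum()
    return 0.5 * float(np.abs(h - np.asarray(mass)).sum())
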