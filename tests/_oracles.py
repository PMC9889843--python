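"""Independent brute-force oracles used by the test suite.

Every oracle minimizes/maximizes by explicit grid enumeration (with
closed-form inner profiling where the contract prescribes it) and never
calls the library's fitting or optimization paths.
"""

from __future__ import annotations

import math

import numpy as np


def grid_search_cosinor(y, t, period=24.0, a_max=5.0, step=0.001):
    """Grid-search SSE minimizer over (A, phi) with closed-form M.

    Enumerates ``A in [0, a_max]`` and ``phi in [0, period)`` on ``step``
    grids; for each pair the SSE-optimal MESOR is the mean of
    ``y - A cos(w (t - phi))``.  Returns ``(A, phi, M)`` of the grid
    minimizer.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    w = 2.0 * math.pi / period
    yc = y - y.mean()
    Syy = float(yc @ yc)
    A_grid = np.arange(0.0, a_max + step / 2, step)
    phi_grid = np.arange(0.0, period, step)

    best = (math.inf, 0.0, 0.0)
    chunk = 512
    for i in range(0, phi_grid.size, chunk):
        phis = phi_grid[i : i + chunk]
        x = np.cos(w * (t[None, :] - phis[:, None]))  # (c, n)
        xc = x - x.mean(axis=1, keepdims=True)
        Sxx = np.einsum("ij,ij->i", xc, xc)
        Sxy = xc @ yc
        # SSE(A, phi) = Syy - 2 A Sxy + A^2 Sxx, quadratic in A
        sse = Syy - 2.0 * A_grid[None, :] * Sxy[:, None] + (
            A_grid[None, :] ** 2
        ) * Sxx[:, None]
        j = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[j] < best[0]:
            best = (float(sse[j]), float(phis[j[0]]), float(A_grid[j[1]]))
    _, phi, A = best
    M = float(np.mean(y - A * np.cos(w * (t - phi))))
    return A, phi, M


def _group_stats(y, t, period, phi_grid):
    """Centered cross-moments of y with cos(w(t - phi)) over a phi grid."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    w = 2.0 * math.pi / period
    yc = y - y.mean()
    x = np.cos(w * (t[None, :] - phi_grid[:, None]))
    xc = x - x.mean(axis=1, keepdims=True)
    Sxx = np.einsum("ij,ij->i", xc, xc)
    Sxy = xc @ yc
    Syy = float(yc @ yc)
    return Sxx, Sxy, Syy, y.size


def _ll_snr_grid(eta, Sxx, Sxy, Syy, n):
    """Profile loglik over phi grid for fixed SNR eta (closed-form M, sigma)."""
    disc = (eta * Sxy) ** 2 + 4.0 * n * Syy
    sigma = (-eta * Sxy + np.sqrt(disc)) / (2.0 * n)
    A = eta * sigma
    rss = Syy - 2.0 * A * Sxy + A * A * Sxx
    return -0.5 * n * np.log(2.0 * math.pi * sigma**2) - rss / (2.0 * sigma**2)


def fitness_constrained_grid(y_I, t_I, y_II, t_II, period=24.0,
                             eta_max=6.0, eta_step=0.002, phi_step=0.002):
    """Max joint loglik under a shared SNR by nested grid enumeration.

    For each eta on a grid the groups decouple, so each group's loglik is
    maximized over its own phi grid (inner M, sigma closed-form); the outer
    maximum over eta is returned.
    """
    phi_grid = np.arange(0.0, period, phi_step)
    gI = _group_stats(y_I, t_I, period, phi_grid)
    gII = _group_stats(y_II, t_II, period, phi_grid)
    best = -math.inf
    for eta in np.arange(0.0, eta_max + eta_step / 2, eta_step):
        ll = _ll_snr_grid(eta, *gI).max() + _ll_snr_grid(eta, *gII).max()
        if ll > best:
            best = ll
    return float(best)


def _gauss_ll(rss, n):
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def global_constrained_grid(y_I, t_I, y_II, t_II, period=24.0,
                            share_mesor=False, halfwidth=1.5, step=0.002):
    """Max joint loglik under shared (a, b) [and M] by grid enumeration.

    Grids (a, b) (and M when shared) around the pooled OLS estimate; the
    remaining per-group parameters (M when free, sigma) are closed-form.
    """
    outs = []
    for y, t in ((y_I, t_I), (y_II, t_II)):
        y = np.asarray(y, float)
        t = np.asarray(t, float)
        w = 2.0 * math.pi / period
        outs.append((y, np.sin(w * t), np.cos(w * t)))
    # center the grid on the pooled OLS fit
    Y = np.concatenate([o[0] for o in outs])
    S = np.concatenate([o[1] for o in outs])
    C = np.concatenate([o[2] for o in outs])
    X = np.column_stack([S, C, np.ones_like(Y)])
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    a_grid = np.arange(beta[0] - halfwidth, beta[0] + halfwidth, step)
    b_grid = np.arange(beta[1] - halfwidth, beta[1] + halfwidth, step)

    best = -math.inf
    if share_mesor:
        m_grid = np.arange(beta[2] - halfwidth, beta[2] + halfwidth, step)
        B, M = np.meshgrid(b_grid, m_grid, indexing="ij")
        for a in a_grid:
            tot = np.zeros_like(B)
            for y, s, c in outs:
                r0 = y - a * s
                n = y.size
                # rss(b, m) expanded in the quadratic cross-moments
                rss = (
                    float(r0 @ r0)
                    - 2.0 * B * float(r0 @ c)
                    - 2.0 * M * float(r0.sum())
                    + B * B * float(c @ c)
                    + 2.0 * B * M * float(c.sum())
                    + M * M * n
                )
                tot += -0.5 * n * (np.log(2 * math.pi * rss / n) + 1.0)
            m = tot.max()
            if m > best:
                best = m
    else:
        for a in a_grid:
            tot_b = np.zeros_like(b_grid)
            for y, s, c in outs:
                r0 = y - a * s
                r0c = r0 - r0.mean()
                cc = c - c.mean()
                n = y.size
                rss = (
                    float(r0c @ r0c)
                    - 2.0 * b_grid * float(r0c @ cc)
                    + b_grid**2 * float(cc @ cc)
                )
                tot_b += -0.5 * n * (np.log(2 * math.pi * rss / n) + 1.0)
            m = tot_b.max()
            if m > best:
                best = m
    return float(best)


def shared_phase_profile_grid(y_I, t_I, y_II, t_II, period=24.0, step=0.001):
    """Joint profile loglik over a shared phase grid (A >= 0, M, sigma free).

    Returns ``(phi_best, loglik_best)`` on a ``step``-resolution grid.
    """
    phi_grid = np.arange(0.0, period, step)
    total = np.zeros_like(phi_grid)
    for y, t in ((y_I, t_I), (y_II, t_II)):
        Sxx, Sxy, Syy, n = _group_stats(y, t, period, phi_grid)
        A = np.clip(Sxy / np.where(Sxx > 0, Sxx, 1.0), 0.0, None)
        rss = Syy - 2.0 * A * Sxy + A * A * Sxx
        total += -0.5 * n * (np.log(2.0 * math.pi * rss / n) + 1.0)
    i = int(np.argmax(total))
    return float(phi_grid[i]), float(total[i])


def shared_amplitude_grid(y_I, t_I, y_II, t_II, period=24.0,
                          a_max=5.0, a_step=0.002, phi_step=0.002):
    """Max joint loglik under a shared amplitude by nested grid enumeration."""
    phi_grid = np.arange(0.0, period, phi_step)
    groups = []
    for y, t in ((y_I, t_I), (y_II, t_II)):
        groups.append(_group_stats(y, t, period, phi_grid))
    best = -math.inf
    for A in np.arange(0.0, a_max + a_step / 2, a_step):
        tot = 0.0
        for Sxx, Sxy, Syy, n in groups:
            rss = Syy - 2.0 * A * Sxy + A * A * Sxx
            tot += (-0.5 * n * (np.log(2.0 * math.pi * rss / n) + 1.0)).max()
        if tot > best:
            best = tot
    return float(best)


def shared_mesor_grid(y_I, t_I, y_II, t_II, period=24.0,
                      halfwidth=3.0, step=0.0005):
    """Max joint loglik under a shared MESOR by 1-D grid enumeration."""
    ys = []
    for y, t in ((y_I, t_I), (y_II, t_II)):
        y = np.asarray(y, float)
        t = np.asarray(t, float)
        w = 2.0 * math.pi / period
        ys.append((y, np.column_stack([np.sin(w * t), np.cos(w * t)])))
    center = np.mean([y.mean() for y, _ in ys])
    best = -math.inf
    for M in np.arange(center - halfwidth, center + halfwidth, step):
        tot = 0.0
        for y, S in ys:
            z = y - M
            coef = np.linalg.lstsq(S, z, rcond=None)[0]
            r = z - S @ coef
            tot += _gauss_ll(float(r @ r), y.size)
        if tot > best:
            best = tot
    return float(best)
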