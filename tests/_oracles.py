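"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the TV-L1 optima come
from exhaustive dynamic programming over quantized images, and the 1-D
least-squares minimum from a brute-force scan.
"""

from __future__ import annotations

import itertools

import numpy as np


def tv_l1_objective_direct(u, f, delta, mask=None):
    """Direct evaluation of Σ|u−f| + δ·Σ√((∂x u)²+(∂y u)²), forward diffs,
    replicate boundary (last row/col differences are zero)."""
    u = np.asarray(u, float)
    f = np.asarray(f, float)
    if mask is None:
        mask = np.ones(u.shape, bool)
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    cx = np.zeros_like(mask)
    cy = np.zeros_like(mask)
    cx[:, :-1] = mask[:, :-1] & mask[:, 1:]
    cy[:-1, :] = mask[:-1, :] & mask[1:, :]
    gx[~cx] = 0.0
    gy[~cy] = 0.0
    return float(np.abs(u - f)[mask].sum() + delta * np.hypot(gx, gy)[mask].sum())


def tv_l1_two_level_optimum(f, levels, delta):
    """Exact TV-L1 optimum over ALL two-level images on f's grid.

    Transfer-matrix dynamic program over column bit-patterns: the objective
    decomposes as a sum of terms coupling each column only to its successor
    (forward differences), so scanning 2^H patterns per column is exhaustive
    over all 2^(H·W) two-level images.  Feasible for H <= ~12.
    """
    f = np.asarray(f, float)
    h, w = f.shape
    v = np.asarray(levels, float)
    assert v.size == 2
    patterns = np.array(list(itertools.product((0, 1), repeat=h)))  # (P, h)
    vals = v[patterns]  # (P, h) column pixel values
    P = len(patterns)

    # data cost of assigning pattern p to column j: (w, P)
    data = np.array(
        [[np.abs(vals[p] - f[:, j]).sum() for p in range(P)] for j in range(w)]
    )

    dy = np.zeros((P, h))
    dy[:, :-1] = vals[:, 1:] - vals[:, :-1]

    # gradient cost of a non-final column with pattern p followed by q: (P, P)
    t_mid = np.empty((P, P))
    for p in range(P):
        dx = vals - vals[p][None, :]  # (P, h): dx toward each successor q
        t_mid[p, :] = delta * np.sqrt(dx**2 + dy[p][None, :] ** 2).sum(axis=1)
    # gradient cost of the final column (dx = 0, replicate boundary): (P,)
    t_last = delta * np.abs(dy).sum(axis=1)

    best = data[0].copy()
    for j in range(w - 1):
        best = (best[:, None] + t_mid).min(axis=0) + data[j + 1]
    return float((best + t_last).min())


def tv_l1_1d_optimum(f, levels, delta):
    """Exact 1-D TV-L1 optimum over sequences quantized to ``levels``.

    For the L1 data term the minimizer takes values among the input's level
    set, so this DP over the input's distinct values is the true optimum.
    """
    f = np.asarray(f, float)
    v = np.asarray(levels, float)
    cost = np.abs(v - f[0])
    for i in range(1, f.size):
        step = np.abs(v[:, None] - v[None, :]) * delta  # (prev, cur)
        cost = (cost[:, None] + step).min(axis=0) + np.abs(v - f[i])
    return float(cost.min())


def ls_1d_brute_force(F, h, lo, hi, n=20001, refine=3):
    """Brute-force scan of ‖h·C − F‖² over C with local refinement."""
    F = np.asarray(F, float)
    h = np.asarray(h, float)
    best = None
    for _ in range(refine):
        cs = np.linspace(lo, hi, n)
        obj = ((h[None, :] * cs[:, None] - F[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(obj))
        best = cs[i]
        span = (hi - lo) / n * 4
        lo, hi = best - span, best + span
    return float(best)
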