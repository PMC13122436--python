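"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the dip oracle solves
the defining minimisation directly by linear programming, the crossing
oracle scans every profile segment, and the density-crossing oracle is a
brute-force grid search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_lp_oracle(sample) -> float:
    """Dip statistic by direct LP: min over unimodal CDFs of sup|F_n − G|.

    For each candidate mode knot k (an atom is allowed at the mode), the
    sup-norm constraints against the ECDF and its left limits, monotonicity,
    convexity left of the mode and concavity right of it are all linear in
    the knot values of G, so minimising d is an LP; the dip is the minimum
    over k.
    """
    x = np.sort(np.asarray(sample, float))
    n = x.size
    best = np.inf
    for k in range(1, n + 1):
        # variables: g_1..g_n (0..n-1), u = G(x_k^-) (n), d (n+1)
        nv = n + 2
        c = np.zeros(nv)
        c[n + 1] = 1.0
        A, b = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for idx, co in coefs:
                row[idx] += co
            A.append(row)
            b.append(rhs)

        D = n + 1
        for i in range(1, n + 1):
            gi = i - 1
            if i == k:
                le([(gi, 1.0), (D, -1.0)], i / n)
                le([(gi, -1.0), (D, -1.0)], -i / n)
            else:
                le([(gi, -1.0), (D, -1.0)], -i / n)  # g_i >= i/n - d
                le([(gi, 1.0), (D, -1.0)], (i - 1) / n)  # g_i <= (i-1)/n + d
        le([(n, 1.0), (D, -1.0)], (k - 1) / n)
        le([(n, -1.0), (D, -1.0)], -(k - 1) / n)
        chain = list(range(0, k - 1)) + [n] + list(range(k - 1, n))
        for a_, b_ in zip(chain[:-1], chain[1:]):
            le([(a_, 1.0), (b_, -1.0)], 0.0)
        left = [(x[i - 1], i - 1) for i in range(1, k)] + [(x[k - 1], n)]
        for (xa, va), (xb, vb), (xc, vc) in zip(left, left[1:], left[2:]):
            le([(vb, (xc - xb) + (xb - xa)), (va, -(xc - xb)), (vc, -(xb - xa))], 0.0)
        right = [(x[i - 1], i - 1) for i in range(k, n + 1)]
        for (xa, va), (xb, vb), (xc, vc) in zip(right, right[1:], right[2:]):
            le([(vb, -((xc - xb) + (xb - xa))), (va, (xc - xb)), (vc, (xb - xa))], 0.0)

        res = linprog(
            c,
            A_ub=np.array(A),
            b_ub=np.array(b),
            bounds=[(0.0, 1.0)] * nv,
            method="highs",
        )
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(best)


def crossing_scan_oracle(radius, values, threshold, direction, start_radius=None):
    """First threshold crossing by exhaustive scan of points and segments."""
    radius = np.asarray(radius, float)
    values = np.asarray(values, float)
    sign = -1.0 if direction == "downward" else 1.0
    v = sign * values
    t = sign * threshold
    start = -np.inf if start_radius is None else start_radius
    candidates = []
    for i in range(len(v)):
        if v[i] == t and radius[i] >= start:
            candidates.append(radius[i])
        if i + 1 < len(v) and v[i] < t < v[i + 1]:
            rc = radius[i] + (t - v[i]) / (v[i + 1] - v[i]) * (radius[i + 1] - radius[i])
            if rc >= start:
                candidates.append(rc)
    return min(candidates) if candidates else None


def density_crossing_grid_oracle(w1, m1, s1, w2, m2, s2, resolution=1e-3):
    """Density-equality point between the means by brute-force grid scan."""
    xs = np.arange(m1, m2, resolution)
    f1 = w1 * np.exp(-0.5 * ((xs - m1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    f2 = w2 * np.exp(-0.5 * ((xs - m2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    diff = f1 - f2
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    return 0.5 * (xs[i] + xs[i + 1])
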