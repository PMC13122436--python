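"""Migratory-phenotype model: multimodality test and early/late cutoff.

Natal-exit fork lengths pool into two pulses — newly emerged fry leaving in
winter storms and larger smolts leaving in spring.  The workflow is:

1. :func:`dip_test` — Hartigan's dip statistic with a bootstrap p-value
   (uniform null resamples of the same n) to establish that the pooled
   natal-exit size distribution is not unimodal.
2. :func:`fit_mixture` — two-component normal mixture by EM (multi-start).
3. :func:`density_crossing` — the fork length where the two weighted
   component densities are equal; this is the early/late-migrant cutoff.
4. :func:`classify_phenotype` — ``early`` iff natal-exit FL ≤ cutoff
   (boundary inclusive).

The dip statistic is the sup-norm distance between the empirical CDF and the
closest unimodal CDF, computed with the greatest-convex-minorant /
least-concave-majorant construction of Hartigan & Hartigan's published
algorithm.  It is implemented here from scratch (no maintained Python
implementation is available) and cross-validated in the test suite against
an independent linear-programming oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "dip_statistic",
    "dip_null_distribution",
    "dip_test",
    "MixtureFit",
    "PhenotypeCutoff",
    "fit_mixture",
    "density_crossing",
    "classify_phenotype",
]


def dip_statistic(sample) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    The dip is ``min_G sup_x |F_n(x) - G(x)|`` over all unimodal CDFs G.  It
    is invariant to permutation of the input and bounded by
    ``[1/(2n), 1/4]`` for samples of n distinct values.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n < 2 or x[-1] == x[0]:
        return 0.0
    return _dip_sorted(x)


def _dip_sorted(x: np.ndarray) -> float:
    """Dip of sorted data via the iterative GCM/LCM modal-interval algorithm.

    Index bookkeeping follows the published Fortran/C routine (1-based
    touchpoint arrays); distances are kept in count units and divided by
    2n at the end.
    """
    n = x.size
    # mn[j]: previous touchpoint of the greatest convex minorant of the
    # ECDF restricted to x[1..j]; mj[k]: next touchpoint of the least
    # concave majorant of x[k..n].  1-based arrays, slot 0 unused.
    xx = np.concatenate(([np.nan], x))  # 1-based view
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (xx[j] - xx[mnj]) * (mnj - mnmnj) < (xx[mnj] - xx[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (xx[k] - xx[mjk]) * (mjk - mjmjk) < (xx[mjk] - xx[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip_cnt = 1.0  # count units; enforces the 1/(2n) floor after division
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)
    while True:
        # touchpoints of the GCM on [low, high], from high down to low,
        # and of the LCM, from low up to high
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = l_gcm
        ix = l_gcm - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = l_lcm
        iv = 2

        # largest vertical separation between the two fitted curves
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # LCM touchpoint below the current GCM chord
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xx[lcmiv] - xx[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xx[gcmix] - xx[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # GCM touchpoint above the current LCM chord
                    lcmiv1 = lcm[iv - 1]
                    dx = (xx[gcmix] - xx[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xx[lcmiv] - xx[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip_cnt:
            break

        # sup distance of the ECDF from the GCM fit on [low, gcm[ig]] ...
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xx[jj] - xx[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # ... and from the LCM fit on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (xx[jj] - xx[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        if dip_cnt < max(dip_l, dip_u):
            dip_cnt = max(dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return float(dip_cnt / (2.0 * n))


def dip_null_distribution(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform(0,1) samples of size n.

    The uniform is the asymptotically least-favourable unimodal null, so
    these resamples calibrate the bootstrap p-value of :func:`dip_test`.
    """
    return np.array([_dip_sorted(np.sort(rng.random(n))) for _ in range(n_boot)])


def dip_test(
    sample,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = 0,
    null_dips: np.ndarray | None = None,
) -> tuple[float, float]:
    """Hartigan's dip test of unimodality.

    Returns ``(D, p)`` where the p-value is the Monte-Carlo tail fraction of
    dips of ``n_boot`` uniform(0,1) samples of the same size (a precomputed
    ``null_dips`` array may be supplied to share one null across calls).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("dip test needs at least 4 observations")
    d = dip_statistic(x)
    if null_dips is None:
        if n_boot < 100:
            warnings.warn(
                f"n_boot={n_boot} gives a coarse p-value; use >= 100", stacklevel=2
            )
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null_dips = dip_null_distribution(x.size, n_boot, rng)
    p = (1.0 + float(np.sum(null_dips >= d))) / (1.0 + null_dips.size)
    return d, p


@dataclass
class MixtureFit:
    """Two-component normal mixture fit (components ordered by mean)."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    converged: bool
    n_iterations: int

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        w1, w2 = self.weights
        m1, m2 = self.means
        s1, s2 = self.sds
        return w1 * _norm_pdf(x, m1, s1) + w2 * _norm_pdf(x, m2, s2)


@dataclass
class PhenotypeCutoff:
    """Early/late-migrant cutoff with the supporting dip-test evidence."""

    cutoff_fl: float
    cutoff_radius: float
    dip_statistic: float
    dip_pvalue: float


def _norm_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2.0 * math.pi))


def _em_once(x, w, m1, m2, s1, s2, tol=1e-8, max_iter=1000, min_sd=None):
    n = x.size
    if min_sd is None:
        min_sd = 1e-6 * float(np.std(x))
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        p1 = w * _norm_pdf(x, m1, s1)
        p2 = (1.0 - w) * _norm_pdf(x, m2, s2)
        tot = p1 + p2
        tot = np.where(tot <= 0, np.finfo(float).tiny, tot)
        r1 = p1 / tot
        new_ll = float(np.sum(np.log(tot)))
        # M-step
        n1 = float(np.sum(r1))
        n2 = n - n1
        if n1 < 1e-10 or n2 < 1e-10:
            raise _Degenerate
        w = n1 / n
        m1 = float(np.sum(r1 * x) / n1)
        m2 = float(np.sum((1 - r1) * x) / n2)
        s1 = math.sqrt(max(float(np.sum(r1 * (x - m1) ** 2) / n1), 0.0))
        s2 = math.sqrt(max(float(np.sum((1 - r1) * (x - m2) ** 2) / n2), 0.0))
        if s1 < min_sd or s2 < min_sd:
            raise _Degenerate
        if abs(new_ll - loglik) < tol:
            loglik = new_ll
            converged = True
            break
        loglik = new_ll
    return w, m1, m2, s1, s2, loglik, converged, it


class _Degenerate(Exception):
    pass


def fit_mixture(
    sample,
    seed: int | np.random.Generator | None = 0,
    n_starts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Fit a two-component normal mixture by multi-start EM.

    One quantile-based start (means at the 25th/75th percentiles) plus
    random starts (means drawn from the data); the best log-likelihood
    wins.  Components are returned ordered by ascending mean.  Raises if
    every start collapses onto a degenerate (zero-variance) component.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 10:
        raise ValueError("mixture fit needs at least 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd0 = float(np.std(x))
    starts = [(0.5, *np.percentile(x, [25, 75]), sd0 / 2, sd0 / 2)]
    for _ in range(max(n_starts - 1, 0)):
        m1, m2 = np.sort(rng.choice(x, size=2, replace=False))
        if m1 == m2:
            m2 = m1 + sd0 / 10
        f = rng.uniform(0.5, 1.5)
        starts.append((rng.uniform(0.2, 0.8), float(m1), float(m2), sd0 * f / 2, sd0 * f / 2))

    best = None
    for w, m1, m2, s1, s2 in starts:
        try:
            res = _em_once(x, w, m1, m2, s1, s2, tol=tol, max_iter=max_iter)
        except _Degenerate:
            continue
        if best is None or res[5] > best[5]:
            best = res
    if best is None:
        raise RuntimeError("all EM starts degenerate")
    w, m1, m2, s1, s2, loglik, converged, it = best
    if m1 > m2:
        w, m1, m2, s1, s2 = 1.0 - w, m2, m1, s2, s1
    return MixtureFit(
        weights=(w, 1.0 - w),
        means=(m1, m2),
        sds=(s1, s2),
        loglik=loglik,
        converged=converged,
        n_iterations=it,
    )


def density_crossing(fit: MixtureFit, tol: float = 1e-6) -> float:
    """Fork length between the component means where the two weighted
    densities are equal (the early/late cutoff).

    Solved on the log-density difference (a quadratic in x, so at most one
    root lies between distinct means when the endpoint signs differ) by
    bracketed root finding.  Raises if the components overlap so heavily
    that neither dominates at its own mean.
    """
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if not m1 < m2:
        raise ValueError("component means must be distinct and ordered")

    def g(x):
        return (
            math.log(w1) - math.log(s1) - 0.5 * ((x - m1) / s1) ** 2
            - (math.log(w2) - math.log(s2) - 0.5 * ((x - m2) / s2) ** 2)
        )

    ga, gb = g(m1), g(m2)
    if ga <= 0 or gb >= 0:
        raise ValueError(
            "no density crossing bracketed between the means "
            "(severely overlapping components)"
        )
    return float(brentq(g, m1, m2, xtol=tol))


def classify_phenotype(natal_exit_fl, cutoff_fl: float):
    """``early`` iff natal-exit FL ≤ cutoff (boundary inclusive), else ``late``."""
    arr = np.asarray(natal_exit_fl, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.isfinite(cutoff_fl):
        raise ValueError("non-finite fork length or cutoff")
    out = np.where(arr <= cutoff_fl, "early", "late")
    return str(out) if np.isscalar(natal_exit_fl) else out
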