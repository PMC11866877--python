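"""Vectorized (across Monte-Carlo replicates) implementations of the four
interval procedures, operating on arrays of observed count tables.

The scalar functions in :mod:`pairedni.tango`, :mod:`pairedni.mi`,
:mod:`pairedni.hybrid` and :mod:`pairedni.gee` are the reference
implementations; these batch versions compute the same quantities
replicate-wise on a (R, 8) count array with columns

    [n00, n01, n10, n11, n0x, n1x, nx0, nx1]

and are exercised against the scalar API in the test suite.  They exist so
the simulation study can evaluate hundreds of scenarios at thousands of
replicates each without a Python-level loop over replicates.

All functions return a dict with at least ``lower``, ``upper`` (NaN where a
replicate failed) and ``ok`` (boolean mask of analyzable replicates).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .simulate import JointPairDistribution, MissingnessSpec

COLUMNS = ("n00", "n01", "n10", "n11", "n0x", "n1x", "nx0", "nx1")

_GEE_MAX_ALPHA = 0.99


def sample_tables(dist: JointPairDistribution, n: int, spec: MissingnessSpec,
                  nrep: int, rng_gen: np.random.Generator,
                  rng_miss: np.random.Generator) -> np.ndarray:
    """Draw ``nrep`` observed count tables, count-level (O(1) in n).

    Complete-pair cells come from ``rng_gen``; the per-pair missingness
    indicator splits each cell trinomially using ``rng_miss``, so the
    underlying pair draws do not depend on the missingness setting.
    """
    out = np.zeros((nrep, 8), dtype=np.int64)
    counts4 = rng_gen.multinomial(n, dist.cells, size=nrep)  # 00,01,10,11
    pv = np.array([spec.p_miss1, spec.p_miss2,
                   1.0 - spec.p_miss1 - spec.p_miss2])
    # column bookkeeping: losing y1 from cell (i,j) -> nx_j; losing y2 -> n_ix
    dest = {(0, 0): (6, 4, 0), (0, 1): (7, 4, 1),
            (1, 0): (6, 5, 2), (1, 1): (7, 5, 3)}
    for cell_idx, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        split = rng_miss.multinomial(counts4[:, cell_idx], pv)
        cx, cix, ckeep = dest[(i, j)]
        out[:, cx] += split[:, 0]
        out[:, cix] += split[:, 1]
        out[:, ckeep] += split[:, 2]
    return out


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# Tango score CI
# ---------------------------------------------------------------------------

def _tango_F(t0, theta, p01h, npp, z, sign):
    """Score-inequality function (theta-t0) +/- z*sigma(t0), decreasing in t0."""
    de = -t0
    a1 = -theta * (1.0 - de) - 2.0 * (p01h + de)
    b1 = de * (1.0 + de) * p01h
    disc = np.maximum(a1 * a1 - 8.0 * b1, 0.0)
    p101 = (-a1 + np.sqrt(disc)) / 4.0
    var = (2.0 * p101 - de - de * de) / npp
    sig = np.sqrt(np.maximum(var, 0.0))
    return (theta - t0) + sign * z * sig


def tango_batch(tables: np.ndarray, alpha: float, n_iter: int = 50) -> dict:
    """Vectorized bisection for the score CI endpoints."""
    c = tables.astype(np.float64)
    npp = c[:, :4].sum(axis=1)
    ok = npp > 0
    npp_safe = np.where(ok, npp, 1.0)
    theta = (c[:, 2] - c[:, 1]) / npp_safe
    p01h = c[:, 1] / npp_safe
    z = float(norm.ppf(1.0 - alpha))

    # lower endpoint: root of (theta - t0) - z*sigma(t0) in [-1, theta]
    lo = np.full(len(c), -1.0)
    hi = theta.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = _tango_F(mid, theta, p01h, npp_safe, z, -1.0) >= 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    lower = 0.5 * (lo + hi)

    # upper endpoint: root of (theta - t0) + z*sigma(t0) in [theta, 1]
    lo = theta.copy()
    hi = np.full(len(c), 1.0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = _tango_F(mid, theta, p01h, npp_safe, z, +1.0) >= 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    upper = 0.5 * (lo + hi)

    lower = np.where(ok, np.clip(lower, -1.0, 1.0), np.nan)
    upper = np.where(ok, np.clip(upper, -1.0, 1.0), np.nan)
    return {"lower": lower, "upper": upper, "estimate": np.where(ok, theta, np.nan),
            "ok": ok}


# ---------------------------------------------------------------------------
# MI Wald
# ---------------------------------------------------------------------------

def mi_batch(tables: np.ndarray, m: int, alpha: float,
             rng: np.random.Generator) -> dict:
    """Vectorized multiple-imputation Wald CI (m imputations, Rubin pooling)."""
    c = tables.astype(np.float64)
    n = c.sum(axis=1)
    npp = c[:, :4].sum(axis=1)
    ok = (npp > 0) & (n > 0)
    R = len(c)

    cells = c[:, :4].copy()
    need_corr = (cells.min(axis=1) == 0) & ok
    cells[need_corr] += 0.5

    c00, c01, c10, c11 = cells[:, 0], cells[:, 1], cells[:, 2], cells[:, 3]
    # guard fully-failed rows with dummies so arithmetic stays finite
    bad = ~ok
    if bad.any():
        for arr in (c00, c01, c10, c11):
            arr[bad] = 1.0

    def model(s0, t0, s1, t1):
        pi0, pi1 = s0 / t0, s1 / t1
        i0 = t0 * pi0 * (1.0 - pi0)
        i1 = t1 * pi1 * (1.0 - pi1)
        return (_logit(pi0), _logit(pi1) - _logit(pi0),
                1.0 / np.sqrt(i0), 1.0 / np.sqrt(i1))

    # y1 | y2 (covariate y2); y2 | y1 (covariate y1)
    b0m, b1m, sa, sb = model(c10, c00 + c10, c11, c01 + c11)
    d0m, d1m, ta, tb = model(c01, c00 + c01, c11, c10 + c11)

    n0x = tables[:, 4]
    n1x = tables[:, 5]
    nx0 = tables[:, 6]
    nx1 = tables[:, 7]

    sum_t = np.zeros(R)
    sum_t2 = np.zeros(R)
    sum_v = np.zeros(R)
    n_safe = np.where(n > 0, n, 1.0)
    for _ in range(m):
        z = rng.standard_normal((R, 4))
        b0 = b0m + sa * z[:, 0]
        b1 = b1m - sa * z[:, 0] + sb * z[:, 1]
        d0 = d0m + ta * z[:, 2]
        d1 = d1m - ta * z[:, 2] + tb * z[:, 3]

        k_x0 = rng.binomial(nx0, _expit(b0))          # imputed y1=1 at y2=0
        k_x1 = rng.binomial(nx1, _expit(b0 + b1))     # imputed y1=1 at y2=1
        k_0x = rng.binomial(n0x, _expit(d0))          # imputed y2=1 at y1=0
        k_1x = rng.binomial(n1x, _expit(d0 + d1))     # imputed y2=1 at y1=1

        f01 = tables[:, 1] + k_0x + (nx1 - k_x1)
        f10 = tables[:, 2] + k_x0 + (n1x - k_1x)
        th = (f10 - f01) / n_safe
        var = ((f01 + f10) / n_safe - th * th) / n_safe
        sum_t += th
        sum_t2 += th * th
        sum_v += var

    theta_bar = sum_t / m
    within = sum_v / m
    between = np.maximum(sum_t2 - m * theta_bar ** 2, 0.0) / (m - 1)
    total = within + (1.0 + 1.0 / m) * between
    z_a = float(norm.ppf(1.0 - alpha))
    half = z_a * np.sqrt(np.maximum(total, 0.0))
    lower = np.where(ok, np.clip(theta_bar - half, -1.0, 1.0), np.nan)
    upper = np.where(ok, np.clip(theta_bar + half, -1.0, 1.0), np.nan)
    return {"lower": lower, "upper": upper,
            "estimate": np.where(ok, theta_bar, np.nan), "ok": ok}


# ---------------------------------------------------------------------------
# Hybrid
# ---------------------------------------------------------------------------

def _wilson(s, t, z):
    p = s / t
    z2n = z * z / t
    center = (p + z2n / 2.0) / (1.0 + z2n)
    half = z * np.sqrt(p * (1.0 - p) / t + z2n / (4.0 * t)) / (1.0 + z2n)
    return p, np.maximum(center - half, 0.0), np.minimum(center + half, 1.0)


def hybrid_batch(tables: np.ndarray, alpha: float) -> dict:
    c = tables.astype(np.float64)
    npp = c[:, :4].sum(axis=1)
    d1 = npp + c[:, 4] + c[:, 5]
    d2 = npp + c[:, 6] + c[:, 7]
    ok = (d1 > 0) & (d2 > 0)
    d1s, d2s = np.where(ok, d1, 1.0), np.where(ok, d2, 1.0)

    n1p = c[:, 2] + c[:, 3]
    n0p = c[:, 0] + c[:, 1]
    np1 = c[:, 1] + c[:, 3]
    np0 = c[:, 0] + c[:, 2]
    marg2 = n1p * n0p * np1 * np0
    rho = np.where(marg2 > 0,
                   (c[:, 3] * c[:, 0] - c[:, 2] * c[:, 1])
                   / np.sqrt(np.where(marg2 > 0, marg2, 1.0)), 0.0)
    rho = np.clip(rho, -1.0, 1.0)

    z = float(norm.ppf(1.0 - alpha))  # z_{alpha/2} at two-sided level 1-2alpha
    p1, l1, u1 = _wilson(n1p + c[:, 5], d1s, z)
    p2, l2, u2 = _wilson(np1 + c[:, 7], d2s, z)
    theta = p1 - p2

    dl1, du1 = p1 - l1, u1 - p1
    dl2, du2 = p2 - l2, u2 - p2
    rad_l = np.maximum(dl1 ** 2 + du2 ** 2 - 2.0 * rho * dl1 * du2, 0.0)
    rad_u = np.maximum(du1 ** 2 + dl2 ** 2 - 2.0 * rho * du1 * dl2, 0.0)
    lower = np.where(ok, np.clip(theta - np.sqrt(rad_l), -1.0, 1.0), np.nan)
    upper = np.where(ok, np.clip(theta + np.sqrt(rad_u), -1.0, 1.0), np.nan)
    return {"lower": lower, "upper": upper,
            "estimate": np.where(ok, theta, np.nan), "ok": ok}


# ---------------------------------------------------------------------------
# GEE
# ---------------------------------------------------------------------------

def gee_batch(tables: np.ndarray, alpha: float, robust: bool = True,
              max_iter: int = 60, tol: float = 1e-12) -> dict:
    """Vectorized exchangeable-working-correlation logistic GEE with
    sandwich covariance and delta-method CI for the risk difference."""
    c = tables.astype(np.float64)
    c00, c01, c10, c11 = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
    c0x, c1x, cx0, cx1 = c[:, 4], c[:, 5], c[:, 6], c[:, 7]
    npp = c00 + c01 + c10 + c11

    T1 = npp + c0x + c1x
    S1 = c10 + c11 + c1x
    T2 = npp + cx0 + cx1
    S2 = c01 + c11 + cx1
    n_clusters = npp + c0x + c1x + cx0 + cx1
    ok = (S1 > 0) & (S1 < T1) & (S2 > 0) & (S2 < T2) & (n_clusters >= 2)

    # benign dummy counts for failed rows keep the vector algebra finite
    if (~ok).any():
        dummy = np.array([5.0, 5.0, 5.0, 5.0, 0.0, 0.0, 0.0, 0.0])
        c = np.where(ok[:, None], c, dummy[None, :])
        c00, c01, c10, c11 = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
        c0x, c1x, cx0, cx1 = c[:, 4], c[:, 5], c[:, 6], c[:, 7]
        npp = c00 + c01 + c10 + c11
        T1 = npp + c0x + c1x
        S1 = c10 + c11 + c1x
        T2 = npp + cx0 + cx1
        S2 = c01 + c11 + cx1

    b0 = _logit(S1 / T1)
    b1 = _logit(S2 / T2) - b0
    aw = np.zeros(len(c))
    n2 = npp  # clusters of size 2
    converged = np.zeros(len(c), dtype=bool)

    def complete_score(mu1, mu2, s1, s2, aw):
        """Summed complete-cluster score contributions (G0c, G1c) and the
        pieces reused for I1; returns per-(i,j) u-components as dict."""
        one_m_a2 = 1.0 - aw * aw
        ratio12 = aw * s1 / s2
        ratio21 = aw * s2 / s1
        u = {}
        for (i, j), w in (((0, 0), c00), ((0, 1), c01),
                          ((1, 0), c10), ((1, 1), c11)):
            r1 = i - mu1
            r2 = j - mu2
            w1 = (r1 - ratio12 * r2) / one_m_a2
            w2 = (r2 - ratio21 * r1) / one_m_a2
            u[(i, j)] = (w1 + w2, w2, w)
        return u

    for it in range(max_iter):
        mu1 = _expit(b0)
        mu2 = _expit(b0 + b1)
        v1 = mu1 * (1.0 - mu1)
        v2 = mu2 * (1.0 - mu2)
        s1 = np.sqrt(v1)
        s2 = np.sqrt(v2)

        # exchangeable moment estimator (complete clusters) before the beta
        # step, so each step is taken under the current working correlation
        num = (c00 * mu1 * mu2 - c01 * mu1 * (1.0 - mu2)
               - c10 * (1.0 - mu1) * mu2 + c11 * (1.0 - mu1) * (1.0 - mu2))
        aw = num / (s1 * s2) / np.maximum(n2 - 2.0, 1.0)
        aw = np.clip(aw, -_GEE_MAX_ALPHA, _GEE_MAX_ALPHA)

        u = complete_score(mu1, mu2, s1, s2, aw)
        G0 = sum(w * u1 for (u1, _, w) in u.values())
        G1 = sum(w * u2 for (_, u2, w) in u.values())
        # singletons
        G0 = G0 + c0x * (0.0 - mu1) + c1x * (1.0 - mu1)
        r2s = cx0 * (0.0 - mu2) + cx1 * (1.0 - mu2)
        G0 = G0 + r2s
        G1 = G1 + r2s

        one_m_a2 = 1.0 - aw * aw
        m11 = (v1 + v2 - 2.0 * aw * s1 * s2) / one_m_a2
        m12 = (v2 - aw * s1 * s2) / one_m_a2
        m22 = v2 / one_m_a2
        w2tot = cx0 + cx1
        I11 = npp * m11 + (c0x + c1x) * v1 + w2tot * v2
        I12 = npp * m12 + w2tot * v2
        I22 = npp * m22 + w2tot * v2

        det = I11 * I22 - I12 * I12
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        db0 = (I22 * G0 - I12 * G1) / det
        db1 = (I11 * G1 - I12 * G0) / det
        b0 = b0 + db0
        b1 = b1 + db1

        if it > 0:
            step = np.maximum(np.abs(db0), np.abs(db1))
            newly = step < tol * (1.0 + np.maximum(np.abs(b0), np.abs(b1)))
            converged = converged | newly
            if bool(np.all(newly)):
                break

    # final information and sandwich pieces at the solution
    mu1 = _expit(b0)
    mu2 = _expit(b0 + b1)
    v1 = mu1 * (1.0 - mu1)
    v2 = mu2 * (1.0 - mu2)
    s1 = np.sqrt(v1)
    s2 = np.sqrt(v2)
    one_m_a2 = 1.0 - aw * aw
    m11 = (v1 + v2 - 2.0 * aw * s1 * s2) / one_m_a2
    m12 = (v2 - aw * s1 * s2) / one_m_a2
    m22 = v2 / one_m_a2
    w2tot = cx0 + cx1
    I11 = npp * m11 + (c0x + c1x) * v1 + w2tot * v2
    I12 = npp * m12 + w2tot * v2
    I22 = npp * m22 + w2tot * v2
    det = I11 * I22 - I12 * I12
    det = np.where(np.abs(det) < 1e-300, 1.0, det)

    u = complete_score(mu1, mu2, s1, s2, aw)
    J11 = sum(w * u1 * u1 for (u1, _, w) in u.values())
    J12 = sum(w * u1 * u2 for (u1, u2, w) in u.values())
    J22 = sum(w * u2 * u2 for (_, u2, w) in u.values())
    # singletons: k=1 -> u=(r,0); k=2 -> u=(r,r)
    J11 = J11 + c0x * mu1 ** 2 + c1x * (1.0 - mu1) ** 2
    k2sq = cx0 * mu2 ** 2 + cx1 * (1.0 - mu2) ** 2
    J11 = J11 + k2sq
    J12 = J12 + k2sq
    J22 = J22 + k2sq

    g0 = v1 - v2
    g1 = -v2
    # w = I0^{-1} g
    w0 = (I22 * g0 - I12 * g1) / det
    w1 = (I11 * g1 - I12 * g0) / det
    if robust:
        se2 = J11 * w0 * w0 + 2.0 * J12 * w0 * w1 + J22 * w1 * w1
    else:
        se2 = g0 * w0 + g1 * w1
    se = np.sqrt(np.maximum(se2, 0.0))
    theta = mu1 - mu2
    z = float(norm.ppf(1.0 - alpha))
    good = ok & converged
    lower = np.where(good, np.clip(theta - z * se, -1.0, 1.0), np.nan)
    upper = np.where(good, np.clip(theta + z * se, -1.0, 1.0), np.nan)
    return {"lower": lower, "upper": upper,
            "estimate": np.where(good, theta, np.nan), "ok": good,
            "alpha_exch": aw, "beta0": b0, "beta1": b1}
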