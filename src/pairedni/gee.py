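"""Marginal logistic GEE for the paired risk difference, including
singleton clusters from half-observed pairs.

Model: logit P(Y_ck = 1 | k) = beta0 + beta1 * I(k=2), fitted by generalized
estimating equations with an exchangeable working correlation.  Every
observed outcome contributes one row; a complete pair is a cluster of size
two and a pair with one missing outcome a singleton cluster.  Because the
marginal success probability does not depend on the missingness indicator
given k, including singletons leaves the estimating equation unbiased under
MCAR and MAR.

The coefficient covariance is either model-based, I0^{-1}, or the sandwich
I0^{-1} I1 I0^{-1} with the per-cluster empirical residual outer product in
the middle; the sandwich is the default ("robust" intervals).  The risk
difference is recovered as

    theta_gee = expit(beta0) - expit(beta0 + beta1)

with a delta-method standard error, and the Wald interval is
theta_gee +/- z_alpha * SE at two-sided level 1 - 2*alpha.

Clusters sharing the same design matrix and outcome vector are collapsed
into weighted cluster types, so fitting cost is independent of n for the
covariate-free paired design (at most eight types).  The design abstraction
permits additional covariate columns, though only the treatment indicator is
exercised here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .data import MISSING, PairOutcome, PairedCountTable, tabulate
from .exceptions import InvalidParameterError, SeparationError
from .results import ConfidenceInterval

logger = logging.getLogger(__name__)

__all__ = [
    "GeeDesign",
    "GeeFit",
    "RdDeltaResult",
    "build_design",
    "gee_fit",
    "rd_from_fit",
    "gee_ci",
]

_MAX_ALPHA = 0.99  # keep the 2x2 exchangeable working correlation invertible


@dataclass(frozen=True)
class GeeDesign:
    """Clustered design collapsed into weighted cluster types.

    ``types`` is a list of (X, y, weight): X an (s, p) design matrix with
    s in {1, 2} rows and intercept first column, y the (s,) outcome vector,
    weight the number of identical clusters.
    """

    types: list[tuple[np.ndarray, np.ndarray, int]]

    @property
    def n_clusters(self) -> int:
        return sum(w for _, _, w in self.types)

    @property
    def n_obs(self) -> int:
        return sum(w * len(y) for _, y, w in self.types)

    @classmethod
    def from_table(cls, table: PairedCountTable) -> "GeeDesign":
        x1 = np.array([[1.0, 0.0]])          # singleton, intervention 1
        x2 = np.array([[1.0, 1.0]])          # singleton, intervention 2
        x12 = np.array([[1.0, 0.0], [1.0, 1.0]])  # complete pair
        types = []
        for (i, j), w in (((0, 0), table.n00), ((0, 1), table.n01),
                          ((1, 0), table.n10), ((1, 1), table.n11)):
            if w:
                types.append((x12, np.array([float(i), float(j)]), w))
        for y, w in ((0.0, table.n0x), (1.0, table.n1x)):
            if w:
                types.append((x1, np.array([y]), w))
        for y, w in ((0.0, table.nx0), (1.0, table.nx1)):
            if w:
                types.append((x2, np.array([y]), w))
        return cls(types=types)


def build_design(pairs: Iterable[PairOutcome]) -> GeeDesign:
    """One row per observed outcome; complete pairs become clusters of size
    two, half-observed pairs singleton clusters."""
    return GeeDesign.from_table(tabulate(pairs))


@dataclass(frozen=True)
class GeeFit:
    beta: np.ndarray
    cov_model: np.ndarray
    cov_sandwich: np.ndarray
    alpha_exch: float
    phi: float
    n_clusters: int
    iterations: int
    converged: bool
    score_norm: float = 0.0


@dataclass(frozen=True)
class RdDeltaResult:
    theta_gee: float
    se: float
    gradient: np.ndarray


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _check_separation(design: GeeDesign) -> None:
    # each intervention group must contain both outcome values
    succ = {0: 0.0, 1: 0.0}
    tot = {0: 0.0, 1: 0.0}
    for X, y, w in design.types:
        for row, yy in zip(X, y):
            k = int(row[1]) if X.shape[1] > 1 else 0
            succ[k] += w * yy
            tot[k] += w
    for k in (0, 1):
        if tot[k] == 0 or succ[k] == 0 or succ[k] == tot[k]:
            raise SeparationError(
                f"intervention group {k + 1} has a constant (or empty) "
                "outcome; GEE fit is not identified")


def _working_inverse(s: int, alpha: float) -> np.ndarray:
    if s == 1:
        return np.array([[1.0]])
    return np.array([[1.0, -alpha], [-alpha, 1.0]]) / (1.0 - alpha * alpha)


def gee_fit(design: GeeDesign, working_alpha: float | None = None,
            estimate_phi: bool = False, max_iter: int = 100,
            tol: float = 1e-10) -> GeeFit:
    """Solve the GEE sum_c D_c' V_c^{-1} (y_c - mu_c) = 0 by Fisher scoring
    alternating with moment re-estimation of the exchangeable correlation.

    ``working_alpha`` fixes the working correlation (e.g. 0 for working
    independence) instead of estimating it; ``estimate_phi`` switches on
    Pearson-residual moment estimation of the dispersion (default: phi = 1,
    the binomial value).
    """
    if design.n_clusters < 2:
        raise InvalidParameterError("need at least 2 clusters")
    _check_separation(design)
    p = design.types[0][0].shape[1]

    # starting values: independence logistic fit = group-proportion logits
    succ = np.zeros(2)
    tot = np.zeros(2)
    for X, y, w in design.types:
        for row, yy in zip(X, y):
            k = int(row[1])
            succ[k] += w * yy
            tot[k] += w
    pr = succ / tot
    beta = np.array([math.log(pr[0] / (1 - pr[0])),
                     math.log(pr[1] / (1 - pr[1])) - math.log(pr[0] / (1 - pr[0]))])
    if p > 2:
        beta = np.concatenate([beta, np.zeros(p - 2)])

    alpha = 0.0 if working_alpha is None else float(working_alpha)
    phi = 1.0
    n2 = sum(w for X, _, w in design.types if X.shape[0] == 2)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # moment updates of the working correlation (and dispersion) come
        # first so the beta step below is taken under the current alpha
        if estimate_phi or working_alpha is None:
            ss = 0.0
            cross = 0.0
            nobs = 0.0
            for X, y, w in design.types:
                mu = _expit(X @ beta)
                e = (y - mu) / np.sqrt(mu * (1.0 - mu))
                ss += w * float(e @ e)
                nobs += w * len(y)
                if len(y) == 2:
                    cross += w * float(e[0] * e[1])
            if estimate_phi:
                phi = ss / max(nobs - p, 1.0)
            if working_alpha is None:
                alpha = cross / (max(n2 - p, 1.0) * phi)
                alpha = min(max(alpha, -_MAX_ALPHA), _MAX_ALPHA)

        I0 = np.zeros((p, p))
        score = np.zeros(p)
        for X, y, w in design.types:
            mu = _expit(X @ beta)
            v = mu * (1.0 - mu)
            rootA = np.sqrt(v)
            Rinv = _working_inverse(len(y), alpha)
            # D' V^{-1} = X' A^{1/2} R^{-1} A^{-1/2} / phi
            B = (X.T * rootA) @ Rinv
            score += w * (B @ ((y - mu) / rootA)) / phi
            I0 += w * (B @ (X.T * rootA).T) / phi
        delta = np.linalg.solve(I0, score)
        beta = beta + delta

        if it > 1 and float(np.max(np.abs(delta))) < tol * (
                1.0 + float(np.max(np.abs(beta)))):
            converged = True
            break
    if not converged:
        logger.warning("GEE did not converge in %d iterations", max_iter)

    # final matrices at the solution
    I0 = np.zeros((p, p))
    I1 = np.zeros((p, p))
    score = np.zeros(p)
    for X, y, w in design.types:
        mu = _expit(X @ beta)
        v = mu * (1.0 - mu)
        rootA = np.sqrt(v)
        Rinv = _working_inverse(len(y), alpha)
        B = (X.T * rootA) @ Rinv
        u = (B @ ((y - mu) / rootA)) / phi
        score += w * u
        I0 += w * (B @ (X.T * rootA).T) / phi
        I1 += w * np.outer(u, u)
    cov_model = np.linalg.inv(I0)
    cov_sandwich = cov_model @ I1 @ cov_model
    cov_model = 0.5 * (cov_model + cov_model.T)
    cov_sandwich = 0.5 * (cov_sandwich + cov_sandwich.T)
    return GeeFit(beta=beta, cov_model=cov_model, cov_sandwich=cov_sandwich,
                  alpha_exch=alpha, phi=phi, n_clusters=design.n_clusters,
                  iterations=it, converged=converged,
                  score_norm=float(np.linalg.norm(score)))


def rd_from_fit(fit: GeeFit, robust: bool = True) -> RdDeltaResult:
    """Risk difference expit(b0) - expit(b0 + b1) with delta-method SE."""
    b0, b1 = fit.beta[0], fit.beta[1]
    mu1 = 1.0 / (1.0 + math.exp(-b0))
    mu2 = 1.0 / (1.0 + math.exp(-(b0 + b1)))
    v1, v2 = mu1 * (1.0 - mu1), mu2 * (1.0 - mu2)
    g = np.zeros_like(fit.beta)
    g[0] = v1 - v2
    g[1] = -v2
    cov = fit.cov_sandwich if robust else fit.cov_model
    se = math.sqrt(max(float(g @ cov @ g), 0.0))
    return RdDeltaResult(theta_gee=mu1 - mu2, se=se, gradient=g)


def gee_ci(pairs_or_table, alpha: float = 0.05,
           robust: bool = True) -> ConfidenceInterval:
    """Delta-method Wald CI for the risk difference from the logistic GEE
    (sandwich covariance by default) at two-sided level 1 - 2*alpha."""
    if not 0.0 < alpha < 0.5:
        raise InvalidParameterError("alpha must be in (0, 0.5)")
    if isinstance(pairs_or_table, PairedCountTable):
        design = GeeDesign.from_table(pairs_or_table)
    elif isinstance(pairs_or_table, GeeDesign):
        design = pairs_or_table
    else:
        design = build_design(pairs_or_table)
    fit = gee_fit(design)
    rd = rd_from_fit(fit, robust=robust)
    z = float(norm.ppf(1.0 - alpha))
    return ConfidenceInterval(
        lower=max(rd.theta_gee - z * rd.se, -1.0),
        upper=min(rd.theta_gee + z * rd.se, 1.0),
        level=1.0 - 2 * alpha, method="gee", n_used=design.n_clusters,
        estimate=rd.theta_gee)
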