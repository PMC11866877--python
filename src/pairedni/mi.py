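"""Multiple imputation of partially observed pairs with a pooled Wald CI.

Missing outcomes are imputed from cross-outcome logistic models fitted on the
complete pairs: logit P(y1=1 | y2) = b0 + b1*y2 and symmetrically for y2
given y1.  For each of m imputed datasets a coefficient vector is drawn from
the asymptotic normal of the fit (mean = MLE, covariance = inverse observed
information), each missing outcome is drawn Bernoulli at the implied
probability, and the complete-data risk-difference estimate and its
unrestricted ML variance  sigma^2 = [(p01 + p10) - theta^2] / n  are computed
on the completed table of all n pairs.  Estimates are pooled by Rubin's
rules (total variance = within + (1 + 1/m) * between) and the interval is
theta_bar +/- z_alpha * sqrt(total variance).

Because the two outcomes are binary, the logistic fits are saturated 2x2
fits with closed-form MLEs (b1 is the log odds ratio) and closed-form
information; no iterative solver is needed.  Zero cells among the complete
pairs are handled by adding 0.5 to each of the four cells for model fitting
only (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, t as t_dist

from .data import PairedCountTable, theta_complete
from .exceptions import InvalidParameterError, SeparationError
from .results import ConfidenceInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationModel",
    "PooledEstimate",
    "fit_imputation_models",
    "impute_once",
    "mi_wald_ci",
]


@dataclass(frozen=True)
class ImputationModel:
    """Logistic model of one outcome given the other, fitted on complete
    pairs; ``cov`` is the inverse observed information of (b0, b1)."""

    beta0: float
    beta1: float
    cov: np.ndarray
    direction: str  # "y1_given_y2" | "y2_given_y1"

    def prob(self, covariate: int) -> float:
        eta = self.beta0 + self.beta1 * covariate
        return 1.0 / (1.0 + math.exp(-eta))

    def draw_coefficients(self, rng: np.random.Generator) -> tuple[float, float]:
        """One draw from N((b0, b1), cov) via the closed-form Cholesky factor."""
        a = self.cov[0, 0]
        l11 = math.sqrt(max(a, 0.0))
        l21 = self.cov[0, 1] / l11 if l11 > 0.0 else 0.0
        l22 = math.sqrt(max(self.cov[1, 1] - l21 * l21, 0.0))
        z1, z2 = rng.standard_normal(2)
        return self.beta0 + l11 * z1, self.beta1 + l21 * z1 + l22 * z2


@dataclass(frozen=True)
class PooledEstimate:
    theta_bar: float
    within_var: float
    between_var: float
    total_var: float
    m: int
    df: float


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _fit_2x2(s0: float, t0: float, s1: float, t1: float,
             direction: str) -> ImputationModel:
    """Saturated logistic fit from (successes, trials) at covariate 0 and 1."""
    pi0, pi1 = s0 / t0, s1 / t1
    i0 = t0 * pi0 * (1.0 - pi0)
    i1 = t1 * pi1 * (1.0 - pi1)
    cov = np.array([[1.0 / i0, -1.0 / i0],
                    [-1.0 / i0, 1.0 / i0 + 1.0 / i1]])
    return ImputationModel(beta0=_logit(pi0), beta1=_logit(pi1) - _logit(pi0),
                           cov=cov, direction=direction)


def fit_imputation_models(
    table: PairedCountTable, zero_cell_correction: bool = True
) -> tuple[ImputationModel, ImputationModel]:
    """Fit the two cross-outcome logistic models on the complete pairs.

    A zero cell among (n00, n01, n10, n11) makes the saturated fit separate;
    by default 0.5 is added to each of the four cells for fitting only.  With
    ``zero_cell_correction=False`` such tables raise :class:`SeparationError`.
    """
    if table.n_pp == 0:
        raise SeparationError("no complete pairs to fit imputation models on")
    cells = (table.n00, table.n01, table.n10, table.n11)
    if min(cells) == 0:
        if not zero_cell_correction:
            raise SeparationError(
                "zero cell among complete pairs; saturated logistic fit is "
                "degenerate (enable zero_cell_correction)")
        logger.info("zero cell among complete pairs; adding 0.5 to each cell "
                    "for imputation-model fitting")
        c00, c01, c10, c11 = (c + 0.5 for c in cells)
    else:
        c00, c01, c10, c11 = cells
    # y1 | y2: covariate is y2
    m1 = _fit_2x2(c10, c00 + c10, c11, c01 + c11, "y1_given_y2")
    # y2 | y1: covariate is y1
    m2 = _fit_2x2(c01, c00 + c01, c11, c10 + c11, "y2_given_y1")
    return m1, m2


def impute_once(table: PairedCountTable,
                models: tuple[ImputationModel, ImputationModel],
                rng: np.random.Generator) -> PairedCountTable:
    """Complete the table once: draw one coefficient vector per model, then
    impute each missing outcome Bernoulli at the implied probability."""
    if table.n_px + table.n_xp == 0:
        return table
    m_y1, m_y2 = models
    if m_y1.direction != "y1_given_y2" or m_y2.direction != "y2_given_y1":
        raise InvalidParameterError("models given in wrong order")
    b0, b1 = m_y1.draw_coefficients(rng)
    c0, c1 = m_y2.draw_coefficients(rng)

    def expit(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-x))

    n00, n01, n10, n11 = table.n00, table.n01, table.n10, table.n11
    # y1 missing, y2 observed -> impute y1 from m_y1
    k = rng.binomial(table.nx0, expit(b0))
    n10, n00 = n10 + k, n00 + (table.nx0 - k)
    k = rng.binomial(table.nx1, expit(b0 + b1))
    n11, n01 = n11 + k, n01 + (table.nx1 - k)
    # y2 missing, y1 observed -> impute y2 from m_y2
    k = rng.binomial(table.n0x, expit(c0))
    n01, n00 = n01 + k, n00 + (table.n0x - k)
    k = rng.binomial(table.n1x, expit(c0 + c1))
    n11, n10 = n11 + k, n10 + (table.n1x - k)
    return PairedCountTable(n00=n00, n01=n01, n10=n10, n11=n11)


def _pool(thetas: list[float], variances: list[float]) -> PooledEstimate:
    m = len(thetas)
    theta_bar = sum(thetas) / m
    within = sum(variances) / m
    between = (sum((t - theta_bar) ** 2 for t in thetas) / (m - 1)
               if m > 1 else 0.0)
    total = within + (1.0 + 1.0 / m) * between
    if between > 0.0 and within > 0.0:
        r = (1.0 + 1.0 / m) * between / within
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
    else:
        df = math.inf
    return PooledEstimate(theta_bar=theta_bar, within_var=within,
                          between_var=between, total_var=total, m=m, df=df)


def mi_wald_ci(table: PairedCountTable, m: int = 10, alpha: float = 0.05,
               rng: np.random.Generator | None = None,
               use_t: bool = False) -> ConfidenceInterval:
    """Pooled Wald CI for the risk difference from m multiply imputed tables.

    With no missing observations this collapses exactly to the single-dataset
    Wald interval theta_cc +/- z_alpha * sigma_hat.  The reference
    distribution is normal by default; ``use_t=True`` switches to the
    Barnard-Rubin t with Rubin degrees of freedom.
    """
    if m < 2:
        raise InvalidParameterError("m must be >= 2")
    if not 0.0 < alpha < 0.5:
        raise InvalidParameterError("alpha must be in (0, 0.5)")
    n = table.n

    def wald_parts(completed: PairedCountTable) -> tuple[float, float]:
        th = theta_complete(completed).value
        p01 = completed.n01 / n
        p10 = completed.n10 / n
        return th, ((p01 + p10) - th * th) / n

    if table.n_px + table.n_xp == 0:
        theta, var = wald_parts(table)
        pooled = PooledEstimate(theta, var, 0.0, var, m, math.inf)
    else:
        if rng is None:
            rng = np.random.default_rng()
        models = fit_imputation_models(table)
        thetas, variances = [], []
        for _ in range(m):
            th, var = wald_parts(impute_once(table, models, rng))
            thetas.append(th)
            variances.append(var)
        pooled = _pool(thetas, variances)

    if use_t and math.isfinite(pooled.df):
        q = float(t_dist.ppf(1.0 - alpha, pooled.df))
    else:
        q = float(norm.ppf(1.0 - alpha))
    half = q * math.sqrt(max(pooled.total_var, 0.0))
    ci = ConfidenceInterval(
        lower=max(pooled.theta_bar - half, -1.0),
        upper=min(pooled.theta_bar + half, 1.0),
        level=1.0 - 2 * alpha, method="mi_wald", n_used=n,
        estimate=pooled.theta_bar)
    return ci
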