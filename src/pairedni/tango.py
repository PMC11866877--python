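"""Score-based inference for the paired risk difference (complete pairs only).

Implements Nam's one-sided score test of H0: theta <= -delta against
H1: theta > -delta, Tango's score confidence interval obtained by inverting
the same standardized score statistic, and the score-test-based asymptotic
sample-size calculation used to plan paired non-inferiority studies.

The score statistic standardizes theta_cc + delta by the restricted-MLE
(RMLE) null variance: with p01_hat the discordant-cell proportion, the RMLEs
of the discordant probabilities at the boundary theta = -delta are

    p101 = [-a1 + sqrt(a1^2 - 8 b1)] / 4,      p110 = p101 - delta,
    a1   = -theta_cc (1 - delta) - 2 (p01_hat + delta),
    b1   = delta (1 + delta) p01_hat,

and the restricted variance is sigma_l^2 = [(p101 + p110) - delta^2] / n.
At delta = 0 the squared statistic reduces exactly to McNemar's chi-square.

The confidence interval solves, over candidate values theta0, the pair of
score inequalities (theta_cc - theta0)/sigma(theta0) = +/- z_alpha, where
sigma(theta0) is the restricted variance with the boundary value -theta0
substituted for -delta.  The standardized score is monotone decreasing in
theta0, so each endpoint is found by bisection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import norm

from .data import PairedCountTable, theta_complete
from .exceptions import (InvalidParameterError, NoInformationError,
                         UndefinedEstimateError)
from .results import ConfidenceInterval

logger = logging.getLogger(__name__)

__all__ = [
    "RmleBoundary",
    "ScoreTestResult",
    "rmle_at_boundary",
    "restricted_variance",
    "nam_score_test",
    "tango_ci",
    "nam_asymptotic_power",
    "nam_sample_size",
]

_BISECT_TOL = 1e-10
_DISC_TOL = 1e-9


@dataclass(frozen=True)
class RmleBoundary:
    """Restricted MLEs of the discordant-cell probabilities at a boundary."""

    p101: float
    p110: float
    a1: float
    b1: float


@dataclass(frozen=True)
class ScoreTestResult:
    statistic: float
    reject: bool
    alpha: float
    delta: float
    sigma_tilde_sq: float


def rmle_at_boundary(p01_hat: float, theta_cc: float,
                     delta_eff: float) -> RmleBoundary:
    """Restricted MLEs of (p101, p110) under the constraint theta = -delta_eff.

    ``delta_eff`` is the boundary value in play: the margin delta for the
    hypothesis test, or -theta0 when inverting the score for the CI.
    """
    if not 0.0 <= p01_hat <= 1.0:
        raise InvalidParameterError(f"p01_hat={p01_hat} outside [0, 1]")
    if not -1.0 <= delta_eff <= 1.0:
        raise InvalidParameterError(f"delta_eff={delta_eff} outside [-1, 1]")
    a1 = -theta_cc * (1.0 - delta_eff) - 2.0 * (p01_hat + delta_eff)
    b1 = delta_eff * (1.0 + delta_eff) * p01_hat
    disc = a1 * a1 - 8.0 * b1
    if disc < -_DISC_TOL:
        raise InvalidParameterError(
            f"negative discriminant {disc} in RMLE quadratic")
    p101 = (-a1 + math.sqrt(max(disc, 0.0))) / 4.0
    # tolerate (only) floating-point overshoot of the parameter space
    if -1e-12 < p101 < 0.0:
        p101 = 0.0
    elif 1.0 < p101 < 1.0 + 1e-12:
        p101 = 1.0
    return RmleBoundary(p101=p101, p110=p101 - delta_eff, a1=a1, b1=b1)


def restricted_variance(p01_hat: float, theta_cc: float, delta_eff: float,
                        n: int) -> float:
    """RMLE null variance of theta_cc at the boundary theta = -delta_eff.

    May be zero or negative in degenerate configurations (no discordance);
    callers decide how to handle that.
    """
    rmle = rmle_at_boundary(p01_hat, theta_cc, delta_eff)
    return ((rmle.p101 + rmle.p110) - delta_eff ** 2) / n


def nam_score_test(table: PairedCountTable, delta: float,
                   alpha: float = 0.05) -> ScoreTestResult:
    """Nam's score test of H0: theta <= -delta on the complete pairs."""
    if delta < 0:
        raise InvalidParameterError("delta must be >= 0")
    if not 0.0 < alpha < 0.5:
        raise InvalidParameterError("alpha must be in (0, 0.5)")
    n = table.n_pp
    if n == 0:
        raise UndefinedEstimateError("no complete pairs")
    theta_cc = theta_complete(table).value
    p01_hat = table.n01 / n
    var = restricted_variance(p01_hat, theta_cc, delta, n)
    if var <= 0.0:
        raise NoInformationError(
            "restricted null variance is not positive; the table carries no "
            "information about theta at this boundary")
    statistic = (theta_cc + delta) / math.sqrt(var)
    z = norm.ppf(1.0 - alpha)
    return ScoreTestResult(statistic=statistic, reject=statistic > z,
                           alpha=alpha, delta=delta, sigma_tilde_sq=var)


def _score(theta0: float, theta_cc: float, p01_hat: float, n: int) -> float:
    """Standardized score at candidate theta0; +/-inf where the restricted
    variance vanishes (monotone-decreasing continuation)."""
    var = restricted_variance(p01_hat, theta_cc, -theta0, n)
    num = theta_cc - theta0
    if var <= 0.0:
        if num > 0.0:
            return math.inf
        if num < 0.0:
            return -math.inf
        return 0.0
    return num / math.sqrt(var)


def _bisect(f, lo: float, hi: float, tol: float = _BISECT_TOL) -> float:
    """Bisection for a decreasing f with f(lo) >= 0 >= f(hi)."""
    flo, fhi = f(lo), f(hi)
    if flo < 0.0:
        return lo
    if fhi > 0.0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tango_ci(table: PairedCountTable, alpha: float = 0.05) -> ConfidenceInterval:
    """Tango's score confidence interval at two-sided level 1 - 2*alpha.

    Endpoints are the roots in theta0 of (theta_cc - theta0)/sigma(theta0)
    = +/- z_alpha, with sigma(theta0) the restricted-MLE standard deviation at
    boundary theta0; found by bisection (the standardized score is monotone
    decreasing in theta0).
    """
    if not 0.0 < alpha < 0.5:
        raise InvalidParameterError("alpha must be in (0, 0.5)")
    n = table.n_pp
    if n == 0:
        raise UndefinedEstimateError("no complete pairs")
    theta_cc = theta_complete(table).value
    p01_hat = table.n01 / n
    if table.n01 + table.n10 == 0:
        # fully concordant: the restricted variance is positive only on one
        # side of 0; the bisection below still resolves both endpoints
        logger.warning("degenerate table (no discordant pairs); score CI "
                       "endpoints follow the limiting score inequality")
    z = norm.ppf(1.0 - alpha)

    lower = _bisect(lambda t0: _score(t0, theta_cc, p01_hat, n) - z,
                    -1.0, theta_cc)
    upper = _bisect(lambda t0: _score(t0, theta_cc, p01_hat, n) + z,
                    theta_cc, 1.0)
    lower = min(max(lower, -1.0), 1.0)
    upper = min(max(upper, -1.0), 1.0)
    return ConfidenceInterval(lower=lower, upper=upper, level=1.0 - 2 * alpha,
                              method="tango", n_used=n, estimate=theta_cc)


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

def _discordant_from_design(p1: float, p2: float, rho: float):
    """Cell probabilities (p10, p01) implied by marginals and correlation."""
    from .simulate import joint_from_marginals  # local import: no cycle at load

    dist = joint_from_marginals(p1, p2, rho)
    return dist.p10, dist.p01


def nam_asymptotic_power(n: int, p10: float, p01: float, delta: float,
                         alpha: float = 0.05) -> float:
    """Asymptotic power of Nam's score test at true discordant cells
    (p10, p01), margin delta, one-sided level alpha.

    Uses the statistic's normal limit: RMLE variance under the boundary null
    (population version, with p01 and theta at their true values) and the
    unrestricted variance under the alternative.
    """
    theta = p10 - p01
    if theta + delta <= 0:
        return alpha if theta + delta == 0 else 0.0
    v1 = (p10 + p01) - theta ** 2
    rmle = rmle_at_boundary(p01, theta, delta)
    v0 = (rmle.p101 + rmle.p110) - delta ** 2
    z_a = norm.ppf(1.0 - alpha)
    return float(norm.cdf(((theta + delta) * math.sqrt(n)
                           - z_a * math.sqrt(v0)) / math.sqrt(v1)))


def nam_sample_size(p1: float, p2: float, rho: float, delta: float,
                    alpha: float = 0.05, power: float = 0.80,
                    p_complete: float = 1.0) -> int:
    """Smallest n for which the asymptotic power of Nam's score test reaches
    ``power``, for a paired design with marginals (p1, p2) and within-pair
    correlation rho.

    ``p_complete`` < 1 inflates the complete-data sample size for a
    complete-case analysis in which only that fraction of patients retain
    both observations: n_total = ceil(n_complete / p_complete).
    """
    if not 0.0 < alpha <= power < 1.0:
        raise InvalidParameterError("need 0 < alpha <= power < 1")
    if not 0.0 < p_complete <= 1.0:
        raise InvalidParameterError("p_complete must be in (0, 1]")
    p10, p01 = _discordant_from_design(p1, p2, rho)
    theta = p10 - p01
    if theta + delta <= 0:
        raise InvalidParameterError(
            "design lies on or below the null boundary; no finite n attains "
            "the target power")
    v1 = (p10 + p01) - theta ** 2
    rmle = rmle_at_boundary(p01, theta, delta)
    v0 = (rmle.p101 + rmle.p110) - delta ** 2
    z_a, z_b = norm.ppf(1.0 - alpha), norm.ppf(power)
    n_real = ((z_a * math.sqrt(v0) + z_b * math.sqrt(v1)) / (theta + delta)) ** 2
    n = max(int(math.ceil(n_real - 1e-9)), 1)
    # guard the ceiling against the power function itself
    while nam_asymptotic_power(n, p10, p01, delta, alpha) < power:
        n += 1
    while n > 1 and nam_asymptotic_power(n - 1, p10, p01, delta, alpha) >= power:
        n -= 1
    if p_complete < 1.0:
        n = int(math.ceil(n / p_complete - 1e-9))
    return n
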