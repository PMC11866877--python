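"""Hybrid Wald-type confidence interval combining complete- and
incomplete-pair information (Tang et al.-style).

The point estimate is the all-observed risk difference.  Variances of the two
margin estimates are back-solved from Wilson score intervals — for a margin
estimate p with Wilson bounds (l, u) at quantile z, Var_l = (p - l)^2 / z^2
and Var_u = (u - p)^2 / z^2 — and combined with an estimate rho of the
within-patient correlation:

    L = theta - sqrt((p1 - l1)^2 + (u2 - p2)^2 - 2 rho (p1 - l1)(u2 - p2))
    U = theta + sqrt((u1 - p1)^2 + (p2 - l2)^2 - 2 rho (u1 - p1)(p2 - l2))

where margin 1 is P(y1=1) estimated from all pairs with y1 observed and
margin 2 is P(y2=1) from all pairs with y2 observed.  rho is estimated as the
phi coefficient of the complete pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import norm

from .data import PairedCountTable, theta_all_observed
from .exceptions import InvalidParameterError, UndefinedEstimateError
from .results import ConfidenceInterval

logger = logging.getLogger(__name__)

__all__ = ["WilsonBounds", "wilson_bounds", "rho_estimate", "hybrid_ci"]


@dataclass(frozen=True)
class WilsonBounds:
    estimate: float
    lower: float
    upper: float
    level_alpha: float  # two-sided alpha; quantile used is z_{alpha/2}


def wilson_bounds(successes: int, trials: int, alpha: float) -> WilsonBounds:
    """Wilson score interval for a binomial proportion at two-sided level
    1 - alpha (quantile z_{alpha/2})."""
    if trials <= 0:
        raise UndefinedEstimateError("Wilson interval needs trials > 0")
    if not 0 <= successes <= trials:
        raise InvalidParameterError("successes outside [0, trials]")
    z = norm.ppf(1.0 - alpha / 2.0)
    p = successes / trials
    z2n = z * z / trials
    center = (p + z2n / 2.0) / (1.0 + z2n)
    half = (z * math.sqrt(p * (1.0 - p) / trials + z2n / (4.0 * trials))
            / (1.0 + z2n))
    return WilsonBounds(estimate=p, lower=max(center - half, 0.0),
                        upper=min(center + half, 1.0), level_alpha=alpha)


def rho_estimate(table: PairedCountTable) -> float:
    """Within-patient correlation: phi coefficient of the complete pairs.

    Returns 0 (with a warning) when a complete-pair margin is degenerate.
    """
    denom2 = table.n1p * table.n0p * table.np1 * table.np0
    if denom2 <= 0:
        logger.warning("degenerate complete-pair margin; rho estimate set to 0")
        return 0.0
    phi = ((table.n11 * table.n00 - table.n10 * table.n01)
           / math.sqrt(denom2))
    return min(max(phi, -1.0), 1.0)


def hybrid_ci(table: PairedCountTable, alpha: float = 0.05) -> ConfidenceInterval:
    """Hybrid Wald-type CI at two-sided level 1 - 2*alpha.

    ``alpha`` is the one-sided level; the Wilson bounds are computed at
    two-sided level 1 - 2*alpha so that the same quantile z_alpha appears in
    the interval and in the back-solved variances.
    """
    if not 0.0 < alpha < 0.5:
        raise InvalidParameterError("alpha must be in (0, 0.5)")
    theta = theta_all_observed(table).value
    rho = rho_estimate(table)

    # margin 1 (P(y1=1)): pairs with y1 observed; margin 2: y2 observed
    w1 = wilson_bounds(table.n1p + table.n1x, table.n_pp + table.n_px,
                       2.0 * alpha)
    w2 = wilson_bounds(table.np1 + table.nx1, table.n_pp + table.n_xp,
                       2.0 * alpha)

    dl1, du1 = w1.estimate - w1.lower, w1.upper - w1.estimate
    dl2, du2 = w2.estimate - w2.lower, w2.upper - w2.estimate

    rad_l = dl1 * dl1 + du2 * du2 - 2.0 * rho * dl1 * du2
    rad_u = du1 * du1 + dl2 * dl2 - 2.0 * rho * du1 * dl2
    if rad_l < 0.0 or rad_u < 0.0:
        logger.warning("negative radicand in hybrid CI (rho=%.3f); clipped "
                       "to 0", rho)
    lower = theta - math.sqrt(max(rad_l, 0.0))
    upper = theta + math.sqrt(max(rad_u, 0.0))
    return ConfidenceInterval(lower=max(lower, -1.0), upper=min(upper, 1.0),
                              level=1.0 - 2 * alpha, method="hybrid",
                              n_used=table.n, estimate=theta)
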