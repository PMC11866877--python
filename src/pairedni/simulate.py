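"""Correlated binary matched-pair generation and MCAR/MAR missingness.

A pair (y1, y2) of Bernoulli outcomes with marginals (p1, p2) and Pearson
(phi) correlation rho has its joint law fully determined by the four cell
probabilities, with

    p11 = p1 p2 + rho * sqrt(p1 (1-p1) p2 (1-p2)),

subject to the Frechet bounds max(0, p1+p2-1) <= p11 <= min(p1, p2).  Pairs
are drawn directly from this four-cell multinomial — for two binary
variables this is distributionally identical to Gaussian-threshold
generators, without their intermediate machinery.

Missingness is imposed per pair by a single three-valued indicator g drawn
multinomially with probabilities (p_miss1, p_miss2, 1 - p_miss1 - p_miss2):
g=1 removes y1, g=2 removes y2, g=3 keeps the pair complete.  At most one
outcome per pair is ever removed, and removal never depends on the outcome
values, so the mechanism is MCAR when the two probabilities are equal and
MAR (arm-dependent) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import MISSING, PairOutcome, PairedCountTable
from .exceptions import InvalidParameterError

__all__ = [
    "JointPairDistribution",
    "MissingnessSpec",
    "joint_from_marginals",
    "generate_pairs",
    "impose_missing",
    "sample_table",
]


@dataclass(frozen=True)
class JointPairDistribution:
    """Joint law of one correlated binary pair."""

    p11: float
    p10: float
    p01: float
    p00: float
    p1: float
    p2: float
    rho: float

    @property
    def cells(self) -> np.ndarray:
        """Cell probabilities in table order (p00, p01, p10, p11)."""
        return np.array([self.p00, self.p01, self.p10, self.p11])


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-arm probabilities that a pair loses its y1 or its y2."""

    p_miss1: float
    p_miss2: float

    def __post_init__(self):
        if self.p_miss1 < 0 or self.p_miss2 < 0:
            raise InvalidParameterError("missingness probabilities must be >= 0")
        if self.p_miss1 + self.p_miss2 > 1.0 + 1e-12:
            raise InvalidParameterError(
                "p_miss1 + p_miss2 must be <= 1 (one indicator draw removes "
                "at most one outcome per pair)")


def joint_from_marginals(p1: float, p2: float,
                         rho: float) -> JointPairDistribution:
    """Cell probabilities implied by marginals (p1, p2) and phi correlation
    rho; raises with the admissible rho range if infeasible."""
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise InvalidParameterError("marginals must lie strictly in (0, 1)")
    s = math.sqrt(p1 * (1.0 - p1) * p2 * (1.0 - p2))
    p11 = p1 * p2 + rho * s
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if p11 < lo - 1e-12 or p11 > hi + 1e-12:
        rho_lo = (lo - p1 * p2) / s
        rho_hi = (hi - p1 * p2) / s
        raise InvalidParameterError(
            f"rho={rho} infeasible for marginals ({p1}, {p2}); admissible "
            f"range is [{rho_lo:.6f}, {rho_hi:.6f}]")
    p11 = min(max(p11, lo), hi)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    return JointPairDistribution(p11=p11, p10=p10, p01=p01, p00=max(p00, 0.0),
                                 p1=p1, p2=p2, rho=rho)


def generate_pairs(dist: JointPairDistribution, n: int,
                   rng: np.random.Generator) -> list[PairOutcome]:
    """n independent draws from the four-cell joint law."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    codes = rng.choice(4, size=n, p=dist.cells)
    lookup = [PairOutcome(0, 0), PairOutcome(0, 1),
              PairOutcome(1, 0), PairOutcome(1, 1)]
    return [lookup[c] for c in codes]


def impose_missing(pairs, spec: MissingnessSpec,
                   rng: np.random.Generator) -> list[PairOutcome]:
    """Remove y1 (prob p_miss1) or y2 (prob p_miss2) per pair, independently
    of the outcome values; never removes a pair's only observation."""
    g = rng.choice(3, size=len(pairs),
                   p=[spec.p_miss1, spec.p_miss2,
                      1.0 - spec.p_miss1 - spec.p_miss2])
    out = []
    for pair, gc in zip(pairs, g):
        if gc == 0 and pair.y2 is not MISSING:
            out.append(PairOutcome(MISSING, pair.y2))
        elif gc == 1 and pair.y1 is not MISSING:
            out.append(PairOutcome(pair.y1, MISSING))
        else:
            out.append(pair)
    return out


def sample_table(dist: JointPairDistribution, n: int, spec: MissingnessSpec,
                 rng_gen: np.random.Generator,
                 rng_miss: np.random.Generator | None = None
                 ) -> PairedCountTable:
    """Draw one observed count table directly at the count level.

    Equivalent in distribution to ``generate_pairs`` followed by
    ``impose_missing``, but O(1) in n: the complete-pair cells are one
    four-cell multinomial draw, and the per-pair missingness indicator
    splits each cell trinomially.  Separate generators for generation and
    missingness keep the underlying pair draws invariant to whether
    missingness is imposed.
    """
    if rng_miss is None:
        rng_miss = rng_gen
    counts4 = rng_gen.multinomial(n, dist.cells)  # order 00, 01, 10, 11
    pv = [spec.p_miss1, spec.p_miss2,
          1.0 - spec.p_miss1 - spec.p_miss2]
    cells = {"n00": 0, "n01": 0, "n10": 0, "n11": 0,
             "n0x": 0, "n1x": 0, "nx0": 0, "nx1": 0}
    for (i, j), c in zip(((0, 0), (0, 1), (1, 0), (1, 1)), counts4):
        lose1, lose2, keep = rng_miss.multinomial(c, pv)
        cells[f"nx{j}"] += int(lose1)
        cells[f"n{i}x"] += int(lose2)
        cells[f"n{i}{j}"] += int(keep)
    return PairedCountTable(**cells)
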