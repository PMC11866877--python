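"""Monte-Carlo evaluation harness: power, coverage and interval width of the
four procedures over a scenario grid, and simulation-based sample-size
search with the conservative monotone rule.

Conventions
-----------
* One-sided hypothesis H0: theta <= -delta at level alpha; every method is
  judged by the same decision surface: reject iff the lower bound of its
  100*(1-2*alpha)% two-sided CI exceeds -delta.
* ``theta`` in a scenario is the true risk difference P(y1=1) - P(y2=1).
  Boundary (type-I error) scenarios set theta = -delta; the deficient arm's
  marginal is base_marginal - delta while the other stays at base_marginal.
* Monte-Carlo SE of a proportion metric is sqrt(p*(1-p)/n_sim).
* Per-scenario randomness derives from (seed, seed_key) via
  ``numpy.random.SeedSequence``; grids assign each scenario
  seed_key=(index,), so results are independent of execution order and
  worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _batch
from .exceptions import InvalidParameterError, NotAchievableError
from .simulate import MissingnessSpec, joint_from_marginals

__all__ = [
    "ScenarioConfig",
    "MethodMetrics",
    "ScenarioResult",
    "run_scenario",
    "run_grid",
    "default_grid",
    "sample_size_search",
]

ALL_METHODS = ("tango", "mi_wald", "hybrid", "gee")

_BATCH_FUNCS = {
    "tango": lambda tables, alpha, rng: _batch.tango_batch(tables, alpha),
    "mi_wald": lambda tables, alpha, rng: _batch.mi_batch(tables, 10, alpha, rng),
    "hybrid": lambda tables, alpha, rng: _batch.hybrid_batch(tables, alpha),
    "gee": lambda tables, alpha, rng: _batch.gee_batch(tables, alpha),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid."""

    n: int
    rho: float
    delta: float
    theta: float            # true risk difference; -delta at the boundary
    p_miss1: float = 0.0
    p_miss2: float = 0.0
    alpha: float = 0.05     # one-sided level
    n_sim: int = 10_000
    seed: int = 0
    seed_key: tuple = ()
    methods: tuple = ALL_METHODS
    base_marginal: float = 0.8

    def marginals(self) -> tuple[float, float]:
        """(p1, p2): the better arm keeps the base marginal, the deficient
        arm is |theta| below it."""
        if self.theta >= 0:
            return self.base_marginal, self.base_marginal - self.theta
        return self.base_marginal + self.theta, self.base_marginal


@dataclass(frozen=True)
class MethodMetrics:
    power: float
    coverage: float
    mean_width: float
    mcse_power: float
    mcse_coverage: float
    n_failed: int
    n_used: int


@dataclass(frozen=True)
class ScenarioResult:
    config: ScenarioConfig
    metrics: dict[str, MethodMetrics]


def _streams(config: ScenarioConfig):
    ss = np.random.SeedSequence(config.seed, spawn_key=config.seed_key)
    gen_ss, miss_ss, mi_ss = ss.spawn(3)
    return (np.random.default_rng(gen_ss), np.random.default_rng(miss_ss),
            np.random.default_rng(mi_ss))


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Estimate power, coverage and mean width of each requested method.

    Replicate-level failures (no complete pairs, GEE separation or
    non-convergence) are excluded from the denominators and reported in
    ``n_failed``.
    """
    if not config.methods:
        raise InvalidParameterError("methods must be nonempty")
    p1, p2 = config.marginals()
    dist = joint_from_marginals(p1, p2, config.rho)
    spec = MissingnessSpec(config.p_miss1, config.p_miss2)
    rng_gen, rng_miss, rng_mi = _streams(config)
    tables = _batch.sample_tables(dist, config.n, spec, config.n_sim,
                                  rng_gen, rng_miss)
    metrics: dict[str, MethodMetrics] = {}
    for method in config.methods:
        res = _BATCH_FUNCS[method](tables, config.alpha, rng_mi)
        ok = res["ok"]
        n_used = int(ok.sum())
        n_failed = config.n_sim - n_used
        if n_used == 0:
            metrics[method] = MethodMetrics(math.nan, math.nan, math.nan,
                                            math.nan, math.nan, n_failed, 0)
            continue
        lower, upper = res["lower"][ok], res["upper"][ok]
        reject = lower > -config.delta
        cover = (lower <= config.theta) & (config.theta <= upper)
        p_rej = float(reject.mean())
        p_cov = float(cover.mean())
        metrics[method] = MethodMetrics(
            power=p_rej,
            coverage=p_cov,
            mean_width=float((upper - lower).mean()),
            mcse_power=math.sqrt(p_rej * (1 - p_rej) / n_used),
            mcse_coverage=math.sqrt(p_cov * (1 - p_cov) / n_used),
            n_failed=n_failed,
            n_used=n_used,
        )
    return ScenarioResult(config=config, metrics=metrics)


def run_grid(configs, n_jobs: int = 1) -> pd.DataFrame:
    """Run every scenario and return one row per scenario x method.

    Deterministic given each config's (seed, seed_key), independent of
    execution order and of ``n_jobs``.
    """
    configs = list(configs)
    if n_jobs != 1:
        from joblib import Parallel, delayed  # optional; sequential default

        results = Parallel(n_jobs=n_jobs)(
            delayed(run_scenario)(c) for c in configs)
    else:
        results = [run_scenario(c) for c in configs]
    rows = []
    for res in results:
        c = res.config
        for method, m in res.metrics.items():
            rows.append({
                "n": c.n, "rho": c.rho, "delta": c.delta, "theta": c.theta,
                "p_miss1": c.p_miss1, "p_miss2": c.p_miss2,
                "alpha": c.alpha, "n_sim": c.n_sim, "method": method,
                "power": m.power, "coverage": m.coverage,
                "mean_width": m.mean_width, "mcse_power": m.mcse_power,
                "mcse_coverage": m.mcse_coverage, "n_failed": m.n_failed,
            })
    return pd.DataFrame(rows)


#: grid defaults mirroring the published simulation study
GRID_N = (20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 300, 400, 507)
GRID_RHO = (0.0, 0.37, 0.5)
#: (delta, theta) combinations: boundary at delta=0.05, and two
#: alternative settings with theta=0
GRID_DELTA_THETA = ((0.05, -0.05), (0.05, 0.0), (0.1, 0.0))
GRID_MISSING = ((0.0, 0.0), (0.15, 0.15), (0.25, 0.25), (0.1, 0.3))


def default_grid(seed: int = 0, n_sim: int = 10_000,
                 methods: tuple = ALL_METHODS) -> list[ScenarioConfig]:
    """The full 468-scenario grid (13 n x 3 rho x 3 (delta, theta) x 4
    missingness settings)."""
    configs = []
    idx = 0
    for n in GRID_N:
        for rho in GRID_RHO:
            for delta, theta in GRID_DELTA_THETA:
                for m1, m2 in GRID_MISSING:
                    configs.append(ScenarioConfig(
                        n=n, rho=rho, delta=delta, theta=theta,
                        p_miss1=m1, p_miss2=m2, n_sim=n_sim, seed=seed,
                        seed_key=(idx,), methods=methods))
                    idx += 1
    return configs


def sample_size_search(method: str, design: ScenarioConfig,
                       target_power: float = 0.80,
                       n_grid=range(500, 701, 2),
                       common_random: bool = True) -> int:
    """Conservative simulation-based sample-size search.

    Estimates power at every n in ``n_grid`` (strictly increasing) with
    ``design.n_sim`` replicates each and returns the smallest n whose power
    exceeds ``target_power`` with all larger grid points also exceeding it.
    With ``common_random=True`` every n reuses the same random streams,
    which removes most replicate-level noise from the shape of the power
    curve.
    """
    n_grid = list(n_grid)
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise InvalidParameterError("n_grid must be strictly increasing")
    powers = []
    for i, n in enumerate(n_grid):
        cfg = replace(design, n=n, methods=(method,),
                      seed_key=design.seed_key if common_random
                      else design.seed_key + (i,))
        powers.append(run_scenario(cfg).metrics[method].power)
    if powers[-1] <= target_power:
        raise NotAchievableError(
            f"power {max(powers):.4f} at best never stays above "
            f"{target_power} on the grid", max_power=max(powers))
    # last grid point at or below target; answer is the next one
    below = [i for i, p in enumerate(powers) if p <= target_power]
    return n_grid[below[-1] + 1] if below else n_grid[0]
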