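"""Shared result containers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ConfidenceInterval:
    """A two-sided 100*(1-2*alpha)% confidence interval for the risk
    difference, produced by one of the four inference procedures.

    ``level`` is the two-sided confidence level (e.g. 0.90 for alpha=0.05
    one-sided).  ``n_used`` is the number of patients contributing to the
    interval (complete pairs for the score method, all patients otherwise).
    """

    lower: float
    upper: float
    level: float
    method: str  # "tango" | "mi_wald" | "hybrid" | "gee"
    n_used: int
    estimate: float | None = None

    def __post_init__(self):
        if self.lower > self.upper + 1e-12:
            raise ValueError(
                f"lower {self.lower} exceeds upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def rejects_noninferiority_null(self, delta: float) -> bool:
        """Decision for H0: theta <= -delta — reject iff lower bound > -delta."""
        return self.lower > -delta

    def covers(self, theta: float) -> bool:
        return self.lower <= theta <= self.upper
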