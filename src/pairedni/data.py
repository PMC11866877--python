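"""Data model for binary matched pairs with missing single observations.

Each patient undergoes two interventions (k = 1, 2) and contributes a pair of
binary outcomes (y1, y2); either outcome — but never both — may be missing.
Observed frequencies live in a 3x3 table whose cells are the four
complete-pair counts ``n00, n01, n10, n11`` and the four half-observed margins
``n0x, n1x`` (y2 missing) and ``nx0, nx1`` (y1 missing).

Two point estimators of the risk difference theta = P(y1=1) - P(y2=1) are
provided: the complete-case estimator (discordant-cell difference over the
complete pairs) and the all-observed estimator that also uses the
half-observed margins.  Both are unbiased under MAR missingness, i.e. when
missingness may depend on the intervention but not on the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Union

import pandas as pd

from .exceptions import BothMissingError, UndefinedEstimateError

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "PairOutcome",
    "PairedCountTable",
    "RiskDifference",
    "tabulate",
    "theta_complete",
    "theta_all_observed",
    "read_pairs",
    "write_pairs",
    "read_table",
    "write_table",
]


class _MissingType:
    """Singleton sentinel for an unobserved outcome (the table's ``x`` code)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


#: Explicit missing-outcome sentinel; never conflated with 0/1.
MISSING = _MissingType()

Outcome = Union[int, _MissingType]


class PairOutcome(NamedTuple):
    """One patient's pair of outcomes; each entry is 0, 1 or :data:`MISSING`."""

    y1: Outcome
    y2: Outcome

    def is_complete(self) -> bool:
        return self.y1 is not MISSING and self.y2 is not MISSING

    def validate(self) -> None:
        for y in (self.y1, self.y2):
            if y is not MISSING and y not in (0, 1):
                raise ValueError(f"outcome must be 0, 1 or MISSING, got {y!r}")
        if self.y1 is MISSING and self.y2 is MISSING:
            raise BothMissingError(f"pair {self!r} has both outcomes missing")


_TABLE_FIELDS = ("n00", "n01", "n10", "n11", "n0x", "n1x", "nx0", "nx1")


@dataclass(frozen=True)
class PairedCountTable:
    """3x3 frequency table of binary matched-pairs outcomes with missingness.

    ``nij`` counts complete pairs with y1=i, y2=j; ``nix`` counts pairs with
    y1=i and y2 missing; ``nxj`` counts pairs with y1 missing and y2=j.
    """

    n00: int = 0
    n01: int = 0
    n10: int = 0
    n11: int = 0
    n0x: int = 0
    n1x: int = 0
    nx0: int = 0
    nx1: int = 0

    def __post_init__(self):
        for name in _TABLE_FIELDS:
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a nonnegative integer")

    # -- derived totals ---------------------------------------------------
    @property
    def n_pp(self) -> int:
        """Number of complete pairs."""
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def n_px(self) -> int:
        """Pairs with y1 observed, y2 missing."""
        return self.n0x + self.n1x

    @property
    def n_xp(self) -> int:
        """Pairs with y1 missing, y2 observed."""
        return self.nx0 + self.nx1

    @property
    def n(self) -> int:
        """Total number of (ingested) pairs."""
        return self.n_pp + self.n_px + self.n_xp

    @property
    def n1p(self) -> int:
        """Complete pairs with y1 = 1."""
        return self.n10 + self.n11

    @property
    def n0p(self) -> int:
        return self.n00 + self.n01

    @property
    def np1(self) -> int:
        """Complete pairs with y2 = 1."""
        return self.n01 + self.n11

    @property
    def np0(self) -> int:
        return self.n00 + self.n10

    # -- conversions ------------------------------------------------------
    def expand(self) -> list[PairOutcome]:
        """Return the multiset of pairs represented by this table."""
        out: list[PairOutcome] = []
        out += [PairOutcome(0, 0)] * self.n00
        out += [PairOutcome(0, 1)] * self.n01
        out += [PairOutcome(1, 0)] * self.n10
        out += [PairOutcome(1, 1)] * self.n11
        out += [PairOutcome(0, MISSING)] * self.n0x
        out += [PairOutcome(1, MISSING)] * self.n1x
        out += [PairOutcome(MISSING, 0)] * self.nx0
        out += [PairOutcome(MISSING, 1)] * self.nx1
        return out

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in _TABLE_FIELDS}

    def complete_only(self) -> "PairedCountTable":
        """Drop the half-observed margins (complete-case sub-table)."""
        return PairedCountTable(self.n00, self.n01, self.n10, self.n11)


@dataclass(frozen=True)
class RiskDifference:
    """Point estimate of theta = P(y1=1) - P(y2=1) with its basis tag."""

    value: float
    basis: str  # "complete_cases" or "all_observed"

    def __post_init__(self):
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"risk difference {self.value} outside [-1, 1]")


def tabulate(pairs: Iterable[PairOutcome]) -> PairedCountTable:
    """Aggregate pair-level records into a :class:`PairedCountTable`.

    Raises :class:`BothMissingError` if a pair has both outcomes missing.
    """
    counts = dict.fromkeys(_TABLE_FIELDS, 0)
    for i, pair in enumerate(pairs):
        if not isinstance(pair, PairOutcome):
            pair = PairOutcome(*pair)
        try:
            pair.validate()
        except BothMissingError as err:
            raise BothMissingError(f"record {i}: {err}") from None
        y1, y2 = pair
        if y1 is MISSING:
            counts[f"nx{y2}"] += 1
        elif y2 is MISSING:
            counts[f"n{y1}x"] += 1
        else:
            counts[f"n{y1}{y2}"] += 1
    return PairedCountTable(**counts)


def theta_complete(table: PairedCountTable) -> RiskDifference:
    """Complete-case risk-difference estimate (n10 - n01) / n_pp."""
    if table.n_pp == 0:
        raise UndefinedEstimateError("no complete pairs: theta_cc undefined")
    return RiskDifference((table.n10 - table.n01) / table.n_pp, "complete_cases")


def theta_all_observed(table: PairedCountTable) -> RiskDifference:
    """All-observed risk-difference estimate.

    (n1+ + n1x)/(n++ + n+x) - (n+1 + nx1)/(n++ + nx+); valid under MAR.
    """
    d1 = table.n_pp + table.n_px
    d2 = table.n_pp + table.n_xp
    if d1 == 0 or d2 == 0:
        raise UndefinedEstimateError("a margin has no observed outcomes")
    value = (table.n1p + table.n1x) / d1 - (table.np1 + table.nx1) / d2
    return RiskDifference(value, "all_observed")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MISSING_CODES = {"", "na", "nan", "x", "."}


def _parse_outcome(v) -> Outcome:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return MISSING
    s = str(v).strip().lower()
    if s in _MISSING_CODES:
        return MISSING
    f = float(s)
    if f not in (0.0, 1.0):
        raise ValueError(f"outcome value {v!r} is not 0/1/missing")
    return int(f)


def read_pairs(path, strict: bool = True) -> list[PairOutcome]:
    """Read pair-level records from delimited text (columns ``id,y1,y2``).

    Comma- or tab-delimited with a header; missing outcomes may be coded as an
    empty field, ``NA`` or ``x``.  With ``strict=False``, pairs with both
    outcomes missing are counted, logged and discarded instead of raising.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("y1", "y2"):
        if required not in cols:
            raise ValueError(f"missing required column {required!r} in {path}")
    pairs: list[PairOutcome] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        pair = PairOutcome(_parse_outcome(row[cols["y1"]]),
                           _parse_outcome(row[cols["y2"]]))
        if pair.y1 is MISSING and pair.y2 is MISSING:
            rec = row[cols["id"]] if "id" in cols else idx
            if strict:
                raise BothMissingError(
                    f"record {rec!r}: both outcomes missing")
            n_dropped += 1
            continue
        pair.validate()
        pairs.append(pair)
    if n_dropped:
        logger.warning("dropped %d pair(s) with both outcomes missing",
                       n_dropped)
    return pairs


def write_pairs(path, pairs: Sequence[PairOutcome]) -> None:
    def fmt(y):
        return "NA" if y is MISSING else str(y)

    df = pd.DataFrame({
        "id": range(1, len(pairs) + 1),
        "y1": [fmt(p.y1) for p in pairs],
        "y2": [fmt(p.y2) for p in pairs],
    })
    df.to_csv(path, index=False)


def read_table(path) -> PairedCountTable:
    """Read an aggregated count table (named cells ``n00 ... nx1``)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [f for f in _TABLE_FIELDS if f not in df.columns]
    if missing:
        raise ValueError(f"table file {path} lacks cells {missing}")
    row = df.iloc[0]
    return PairedCountTable(**{f: int(row[f]) for f in _TABLE_FIELDS})


def write_table(path, table: PairedCountTable) -> None:
    pd.DataFrame([table.as_dict()]).to_csv(path, index=False)
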