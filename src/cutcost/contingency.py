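"""2x2 decision-table semantics: cells, margins and derived rates.

A diagnostic marker with cut-off ``c`` classifies a subject positive
when their score is >= c (ties at the cut-off count as positive). Each
cut-off therefore induces a 2x2 table of test outcome against disease
state with cells TP, FP, TN, FN. Counts are the canonical
representation; proportions are a derived view, which avoids
accumulating rounding error when tables are combined or re-weighted.

From one table four rates follow:

* sensitivity  SE = TP / (TP + FN)   (diseased classified positive)
* specificity  SP = TN / (TN + FP)   (healthy classified negative)
* prevalence   P  = (TP + FN) / N
* level        Q  = (TP + FP) / N    (share of all subjects positive)

which are tied together by Q = SE*P + (1 - SP)*(1 - P).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidTableError, UndefinedRateError

__all__ = [
    "ConfusionTable",
    "Rates",
    "ThresholdProfile",
    "NonMonotoneRatesWarning",
    "table_from_counts",
    "rates_of",
    "profile_from_scores",
]

_TOL = 1e-12


class NonMonotoneRatesWarning(UserWarning):
    """SE fails to be non-increasing (or SP non-decreasing) along the
    ordered thresholds of a profile. Real tables may tie or wobble, so
    this is a warning, not an error."""


@dataclass(frozen=True)
class ConfusionTable:
    """Cell counts of test outcome x disease state at one threshold.

    Cells may be fractional (a proportion view is itself a valid
    table); they must be non-negative and sum to a positive total.
    """

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in cells):
            raise InvalidTableError(f"negative cell in {cells}")
        if sum(cells) <= 0:
            raise InvalidTableError("table total must be positive")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def as_proportions(self) -> "ConfusionTable":
        """The proportion view: cells divided by the total (sums to 1)."""
        n = self.total
        return ConfusionTable(self.tp / n, self.fp / n, self.tn / n, self.fn / n)


@dataclass(frozen=True)
class Rates:
    """Sensitivity, specificity, level and prevalence of one table."""

    se: float
    sp: float
    q: float
    p: float

    def __post_init__(self) -> None:
        for name in ("se", "sp", "q", "p"):
            v = getattr(self, name)
            if not (-_TOL <= v <= 1 + _TOL):
                raise InvalidTableError(f"{name}={v} outside [0, 1]")


def table_from_counts(tp: float, fp: float, tn: float, fn: float) -> ConfusionTable:
    """Build a validated confusion table from four cell counts."""
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


def rates_of(table: ConfusionTable) -> Rates:
    """Derive (SE, SP, Q, P) from a table.

    Raises :class:`UndefinedRateError` naming the empty margin when the
    table contains no diseased or no healthy subjects.
    """
    diseased = table.tp + table.fn
    healthy = table.tn + table.fp
    if diseased <= 0:
        raise UndefinedRateError("diseased margin (tp + fn) is empty; SE undefined")
    if healthy <= 0:
        raise UndefinedRateError("healthy margin (tn + fp) is empty; SP undefined")
    n = table.total
    return Rates(
        se=table.tp / diseased,
        sp=table.tn / healthy,
        q=(table.tp + table.fp) / n,
        p=diseased / n,
    )


@dataclass(frozen=True)
class ThresholdProfile:
    """Ordered candidate cut-offs, each with its confusion table.

    Prevalence must be identical across the tables of one profile (they
    describe the same population). SE is expected to be non-increasing
    and SP non-decreasing as the cut-off rises; violations trigger a
    :class:`NonMonotoneRatesWarning`.
    """

    thresholds: tuple
    tables: tuple = field(repr=False)

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size == 0:
            raise InvalidTableError("profile needs at least one threshold")
        if thr.size != len(self.tables):
            raise InvalidTableError("one table per threshold required")
        if np.any(np.diff(thr) <= 0):
            raise InvalidTableError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", tuple(thr.tolist()))
        object.__setattr__(self, "tables", tuple(self.tables))
        rates = [rates_of(t) for t in self.tables]
        p0 = rates[0].p
        for c, r in zip(self.thresholds, rates):
            if abs(r.p - p0) > _TOL:
                raise InvalidTableError(
                    f"prevalence varies within profile: {r.p} at c={c} vs {p0}"
                )
        se = np.array([r.se for r in rates])
        sp = np.array([r.sp for r in rates])
        if np.any(np.diff(se) > _TOL) or np.any(np.diff(sp) < -_TOL):
            warnings.warn(
                "SE should be non-increasing and SP non-decreasing as the "
                "cut-off rises; this profile violates that ordering",
                NonMonotoneRatesWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.thresholds)

    @property
    def prevalence(self) -> float:
        return rates_of(self.tables[0]).p

    def rates(self) -> list[Rates]:
        return [rates_of(t) for t in self.tables]


def profile_from_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float],
) -> ThresholdProfile:
    """Tabulate a continuous marker at each candidate cut-off.

    ``labels`` are binary disease indicators (1 = diseased); a subject
    is positive when score >= c. Both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0 or s.shape != y.shape:
        raise InvalidTableError("scores and labels must be equal-length, non-empty")
    if not set(np.unique(y)) <= {0, 1}:
        raise InvalidTableError("labels must be binary 0/1")
    if y.sum() == 0:
        raise UndefinedRateError("diseased margin is empty; SE undefined")
    if y.sum() == y.size:
        raise UndefinedRateError("healthy margin is empty; SP undefined")
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0 or np.any(np.diff(thr) <= 0):
        raise InvalidTableError("thresholds must be non-empty and strictly increasing")
    diseased = y == 1
    tables = []
    for c in thr:
        pos = s >= c
        tables.append(
            ConfusionTable(
                tp=int(np.sum(pos & diseased)),
                fp=int(np.sum(pos & ~diseased)),
                tn=int(np.sum(~pos & ~diseased)),
                fn=int(np.sum(~pos & diseased)),
            )
        )
    return ThresholdProfile(thresholds=tuple(thr.tolist()), tables=tuple(tables))
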