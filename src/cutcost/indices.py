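"""Threshold-selection indices and the misclassification-cost ratio.

The indices implemented here:

* **Youden's J** = SE + SP - 1, maximized over cut-offs.
* **Expected cost** EC = C_FP*FP + C_FN*FN - B_TN*TN - B_TP*TP on the
  proportion view; minimized. Benefits and costs are stored as
  non-negative magnitudes, costs entering with + and benefits with -.
* **Cost ratio** r in [0, 1]: the share of total classification stakes
  attached to diseased subjects,
  r = (B_TP + C_FN) / (B_TP + C_FN + B_TN + C_FP).
  r near 1 means outcomes for the diseased dominate, r near 0 the
  healthy; r = 0.5 weighs both classes equally.
* **Rescaled expected cost** EC' = P*SE*r + (1-P)*SP*(1-r)
  = TP*r + TN*(1-r) on proportions; maximized. Minimizing EC and
  maximizing EC' pick the same cut-off.
* **Weighted kappa** kappa(r) = (TN*TP - FN*FP) /
  (r*P*(1-Q) + (1-r)*(1-P)*Q) on proportions (Kraemer's cost-calibrated,
  chance-corrected agreement between test and diagnosis); maximized.
* **Log odds ratio** ln((TN*TP)/(FN*FP)); prevalence-free, and for that
  very reason unsuitable as a cost-aware selection criterion.

The central identity: kappa(1 - P) equals J for every table, so
maximizing J is decision theory with the implicit, prevalence-dependent
cost ratio r = 1 - P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .contingency import ConfusionTable, Rates, rates_of
from .exceptions import (
    CutcostError,
    DegeneratePopulationError,
    IndifferentCostsError,
    UndefinedKappaError,
    UndefinedLogOddsError,
)

__all__ = [
    "CostSpec",
    "IndexValue",
    "youden_j",
    "cost_ratio",
    "expected_cost",
    "rescaled_expected_cost",
    "weighted_kappa",
    "implicit_cost_ratio_of_j",
    "log_odds_ratio",
]


@dataclass(frozen=True)
class CostSpec:
    """Benefits of correct and costs of incorrect classification.

    All four values are non-negative magnitudes per subject:
    ``b_tp``/``b_tn`` the benefit of a true positive/negative,
    ``c_fp``/``c_fn`` the cost of a false positive/negative. At least
    one outcome pair must distinguish correct from incorrect.
    """

    b_tp: float = 0.0
    b_tn: float = 0.0
    c_fp: float = 0.0
    c_fn: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b_tp", "b_tn", "c_fp", "c_fn"):
            if getattr(self, name) < 0:
                raise CutcostError(f"{name} must be a non-negative magnitude")
        if self.b_tp + self.c_fn <= 0 and self.b_tn + self.c_fp <= 0:
            raise IndifferentCostsError(
                "all benefits and costs are zero; no outcome pair "
                "distinguishes correct from incorrect classification"
            )


@dataclass(frozen=True)
class IndexValue:
    """A named index value, with the cost ratio it used (if any)."""

    name: str
    value: float
    r_used: float | None = None


def youden_j(rates: Rates) -> IndexValue:
    """Youden's J = SE + SP - 1, in [-1, 1]."""
    return IndexValue("j", rates.se + rates.sp - 1.0)


def cost_ratio(costs: CostSpec) -> float:
    """The cost ratio r in [0, 1] implied by a benefit/cost spec.

    r = (b_tp + c_fn) / (b_tp + c_fn + b_tn + c_fp): the stakes of
    classifying a diseased subject (benefit of getting it right plus
    cost of getting it wrong) as a share of the total stakes.
    """
    diseased_stakes = costs.b_tp + costs.c_fn
    healthy_stakes = costs.b_tn + costs.c_fp
    denom = diseased_stakes + healthy_stakes
    if denom <= 0:
        raise IndifferentCostsError("total stakes are zero; r undefined")
    return diseased_stakes / denom


def expected_cost(table: ConfusionTable, costs: CostSpec) -> IndexValue:
    """Expected cost per subject; lower is better.

    Computed on the proportion view: costs enter with +, benefits
    with -. With unit error costs and zero benefits this is the
    misclassification probability.
    """
    p = table.as_proportions()
    value = (
        costs.c_fp * p.fp
        + costs.c_fn * p.fn
        - costs.b_tn * p.tn
        - costs.b_tp * p.tp
    )
    return IndexValue("ec", value, r_used=cost_ratio(costs))


def rescaled_expected_cost(rates: Rates, r: float) -> IndexValue:
    """Rescaled expected cost EC' = P*SE*r + (1-P)*SP*(1-r); higher is
    better. Equals TP*r + TN*(1-r) on the proportion view."""
    if not 0.0 <= r <= 1.0:
        raise CutcostError(f"cost ratio r={r} outside [0, 1]")
    value = rates.p * rates.se * r + (1.0 - rates.p) * rates.sp * (1.0 - r)
    return IndexValue("ec_prime", value, r_used=r)


def weighted_kappa(table: ConfusionTable, r: float) -> IndexValue:
    """Kraemer's weighted kappa kappa(r); higher is better.

    kappa(r) = (TN*TP - FN*FP) / (r*P*(1-Q) + (1-r)*(1-P)*Q) with cells
    as proportions. It is a chance-corrected agreement between test and
    diagnosis calibrated to the cost ratio r, lies in [0, 1] whenever
    J >= 0, and reduces to Youden's J at r = 1 - P.
    """
    if not 0.0 <= r <= 1.0:
        raise CutcostError(f"cost ratio r={r} outside [0, 1]")
    c = table.as_proportions()
    rt = rates_of(table)
    denom = r * rt.p * (1.0 - rt.q) + (1.0 - r) * (1.0 - rt.p) * rt.q
    if denom <= 0:
        raise UndefinedKappaError(
            f"kappa denominator is zero at r={r} (level Q={rt.q}, "
            f"prevalence P={rt.p})"
        )
    value = (c.tn * c.tp - c.fn * c.fp) / denom
    return IndexValue("kappa", value, r_used=r)


def implicit_cost_ratio_of_j(p: float) -> float:
    """The cost ratio Youden's J implicitly employs: r = 1 - P.

    Maximizing J over cut-offs is equivalent to expected-cost decision
    theory with this prevalence-dependent ratio: at low prevalence
    errors on the diseased are weighed more heavily (r > 0.5), at high
    prevalence errors on the healthy (r < 0.5), and only at P = 0.5 are
    the two error types weighed equally.
    """
    if not 0.0 < p < 1.0:
        raise DegeneratePopulationError(
            f"prevalence {p} is degenerate; population holds one class"
        )
    return 1.0 - p


def log_odds_ratio(table: ConfusionTable) -> IndexValue:
    """Natural log of the odds ratio (TN*TP)/(FN*FP).

    Identical for counts and proportions, and for any two tables
    sharing (SE, SP) regardless of prevalence. Zero cells raise; no
    continuity correction is applied (callers wanting +0.5 corrections
    must pre-adjust the cells).
    """
    if min(table.tp, table.fp, table.tn, table.fn) <= 0:
        raise UndefinedLogOddsError(
            "a confusion-table cell is zero; the log odds ratio is "
            "infinite or undefined"
        )
    value = (
        math.log(table.tn)
        + math.log(table.tp)
        - math.log(table.fn)
        - math.log(table.fp)
    )
    return IndexValue("log_or", value)
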