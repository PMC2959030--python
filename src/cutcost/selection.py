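"""Threshold ranking under each criterion, and the ROC slope condition.

A criterion assigns one real value per candidate cut-off; the optimum
is the maximizing (or, for expected cost, minimizing) cut-off. Ties are
broken toward the smallest cut-off — the more sensitive operating
point — and every co-optimal cut-off is reported.

For a continuous marker, maximizing EC' (equivalently minimizing EC)
means operating where the ROC curve's slope equals

    m = (1 - P)(1 - r) / (P * r),

i.e. where the diseased/healthy density ratio equals m. With J's
implicit ratio r = 1 - P the target slope is exactly 1 for every
prevalence. For a binormal marker the crossing is found numerically on
the log density ratio (quadratic in the threshold, so up to two roots;
the root maximizing EC' is returned).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .contingency import ThresholdProfile, rates_of
from .exceptions import (
    CutcostError,
    DegeneratePopulationError,
    NoSolutionError,
    SelectionError,
)
from .indices import (
    CostSpec,
    cost_ratio,
    expected_cost,
    log_odds_ratio,
    rescaled_expected_cost,
    weighted_kappa,
    youden_j,
)

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import BinormalModel

__all__ = [
    "CRITERIA",
    "SelectionResult",
    "select_threshold",
    "roc_slope_target",
    "binormal_optimal_threshold",
]

_TIE_TOL = 1e-12

#: criterion name -> (optimization sense, needs r, needs CostSpec)
CRITERIA = {
    "max_j": ("max", False, False),
    "max_kappa": ("max", True, False),
    "min_ec": ("min", False, True),
    "max_ec_prime": ("max", True, False),
    "max_log_or": ("max", False, False),
}


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of ranking a profile's thresholds under one criterion."""

    criterion: str
    r_used: float | None
    values: tuple
    chosen: float
    ties: tuple

    def optimum(self) -> float:
        sense = CRITERIA[self.criterion][0]
        return min(self.values) if sense == "min" else max(self.values)


def _criterion_value(table, criterion, r, costs):
    rt = rates_of(table)
    if criterion == "max_j":
        return youden_j(rt).value
    if criterion == "max_kappa":
        return weighted_kappa(table, r).value
    if criterion == "min_ec":
        return expected_cost(table, costs).value
    if criterion == "max_ec_prime":
        return rescaled_expected_cost(rt, r).value
    if criterion == "max_log_or":
        return log_odds_ratio(table).value
    raise CutcostError(f"unknown criterion {criterion!r}")


def select_threshold(
    profile: ThresholdProfile,
    criterion: str,
    r: float | CostSpec | None = None,
) -> SelectionResult:
    """Rank a profile's cut-offs under ``criterion`` and pick the optimum.

    ``r`` may be a scalar cost ratio or a :class:`CostSpec` (reduced to
    its ratio where a ratio suffices). ``max_kappa`` and
    ``max_ec_prime`` require a ratio; ``min_ec`` requires a full
    :class:`CostSpec` since the ratio alone does not fix EC. The chosen
    cut-off is the smallest among ties; all co-optimal cut-offs (within
    1e-12 of the optimum) are listed in ``ties``.
    """
    if criterion not in CRITERIA:
        raise CutcostError(
            f"unknown criterion {criterion!r}; expected one of {sorted(CRITERIA)}"
        )
    sense, needs_r, needs_costs = CRITERIA[criterion]
    costs = r if isinstance(r, CostSpec) else None
    if needs_costs and costs is None:
        raise CutcostError(f"{criterion} requires a full CostSpec, not a ratio")
    r_scalar: float | None = None
    if needs_r:
        if costs is not None:
            r_scalar = cost_ratio(costs)
        elif r is None:
            raise CutcostError(f"{criterion} requires a cost ratio r")
        else:
            r_scalar = float(r)
    elif costs is not None:
        r_scalar = cost_ratio(costs)

    values = []
    for c, table in zip(profile.thresholds, profile.tables):
        try:
            values.append(_criterion_value(table, criterion, r_scalar, costs))
        except CutcostError as err:
            raise SelectionError(
                f"{criterion} undefined at threshold c={c}: {err}"
            ) from err
    arr = np.asarray(values)
    opt = arr.min() if sense == "min" else arr.max()
    tie_mask = np.abs(arr - opt) <= _TIE_TOL
    ties = tuple(np.asarray(profile.thresholds)[tie_mask].tolist())
    return SelectionResult(
        criterion=criterion,
        r_used=r_scalar,
        values=tuple(arr.tolist()),
        chosen=ties[0],
        ties=ties,
    )


def roc_slope_target(p: float, r: float) -> float:
    """Target ROC slope (1-P)(1-r)/(P*r) of the expected-cost optimum.

    With r = 1 - P (Youden's implicit ratio) the target is 1 for every
    prevalence.
    """
    if not 0.0 < p < 1.0:
        raise DegeneratePopulationError(f"prevalence {p} must be interior")
    if not 0.0 < r < 1.0:
        raise CutcostError(f"cost ratio {r} must be strictly inside (0, 1)")
    return (1.0 - p) * (1.0 - r) / (p * r)


def _log_density_ratio(x, model):
    """log f_diseased(x) - log f_healthy(x) for a binormal model."""
    return norm.logpdf(x, model.mu_diseased, model.sigma_diseased) - norm.logpdf(
        x, model.mu_healthy, model.sigma_healthy
    )


def _theoretical_ec_prime(c, model, r):
    se = norm.sf(c, model.mu_diseased, model.sigma_diseased)
    sp = norm.cdf(c, model.mu_healthy, model.sigma_healthy)
    p = model.prevalence
    return p * se * r + (1.0 - p) * sp * (1.0 - r)


def binormal_optimal_threshold(model: "BinormalModel", r: float) -> float:
    """Expected-cost-optimal cut-off of a binormal marker.

    Solves f_D(c)/f_H(c) = (1-P)(1-r)/(P*r) on the log scale by
    bisection inside [min mean - 10*max sigma, max mean + 10*max sigma]
    to |f| < 1e-9. The log ratio is quadratic when the class variances
    differ, so up to two crossings exist; the one maximizing the
    theoretical EC' is returned. With equal variances the closed form

        c = (mu_H + mu_D)/2 + sigma^2 * ln(m) / (mu_D - mu_H)

    is the unique crossing and agrees with the numerical root.
    """
    if model.mu_diseased <= model.mu_healthy:
        raise NoSolutionError(
            "binormal solver requires the diseased mean above the healthy "
            "mean (score >= c positivity rule)"
        )
    m = roc_slope_target(model.prevalence, r)
    log_m = math.log(m)
    smax = max(model.sigma_healthy, model.sigma_diseased)
    lo = min(model.mu_healthy, model.mu_diseased) - 10.0 * smax
    hi = max(model.mu_healthy, model.mu_diseased) + 10.0 * smax

    grid = np.linspace(lo, hi, 4001)
    g = _log_density_ratio(grid, model) - log_m
    sign_change = np.nonzero(np.diff(np.sign(g)) != 0)[0]
    roots = []
    for i in sign_change:
        root = brentq(
            lambda x: _log_density_ratio(x, model) - log_m,
            grid[i],
            grid[i + 1],
            xtol=1e-12,
        )
        if abs(_log_density_ratio(root, model) - log_m) < 1e-9:
            roots.append(root)
    if not roots:
        raise NoSolutionError(
            f"no density-ratio crossing of slope target {m} in "
            f"[{lo}, {hi}]",
            crossings=roots,
        )
    return max(roots, key=lambda c: _theoretical_ec_prime(c, model, r))
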