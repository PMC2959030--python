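"""Synthetic marker data and exactly-constructed worked examples.

Two generators live here:

* a stochastic binormal marker model (class-conditional normal scores,
  labels drawn at the model prevalence) for statistical tests, and
* deterministic constructors that realize requested (SE, SP) rows as
  exact integer confusion tables, for worked examples where every cell
  must be reproducible.

``scenario_profile`` bundles a pair of 120-subject single-threshold
tables at 25% and 75% prevalence sharing SE = 0.8 and SP = 0.4 — the
canonical demonstration that prevalence-free rates hide
prevalence-dependent costs: Youden's J and the odds ratio coincide
across the pair while kappa(0.5) does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contingency import ConfusionTable, ThresholdProfile
from .exceptions import CutcostError, RealizabilityError

__all__ = [
    "BinormalModel",
    "binormal_sample",
    "scenario_profile",
    "matched_prevalence_pair",
]

#: (TN, FP, FN, TP) cells of the bundled worked-example tables, one
#: cut-off each, 120 subjects, identical SE/SP at the two prevalences.
_SCENARIOS = {
    "prev25": ConfusionTable(tp=24, fp=54, tn=36, fn=6),
    "prev75": ConfusionTable(tp=72, fp=18, tn=12, fn=18),
}


@dataclass(frozen=True)
class BinormalModel:
    """Class-conditional normal marker model at a fixed prevalence."""

    mu_healthy: float = 0.0
    sigma_healthy: float = 1.0
    mu_diseased: float = 1.0
    sigma_diseased: float = 1.0
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_healthy <= 0 or self.sigma_diseased <= 0:
            raise CutcostError("sigmas must be strictly positive")
        if not 0.0 < self.prevalence < 1.0:
            raise CutcostError("prevalence must be strictly inside (0, 1)")


def binormal_sample(
    model: BinormalModel, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (score, label) pairs from a binormal model.

    Labels are Bernoulli(prevalence); scores come from the matching
    class-conditional normal. The seed is a mandatory parameter (no
    global state): identical seeds give identical samples.
    """
    if n <= 0:
        raise CutcostError("sample size must be positive")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < model.prevalence).astype(int)
    mu = np.where(labels == 1, model.mu_diseased, model.mu_healthy)
    sigma = np.where(labels == 1, model.sigma_diseased, model.sigma_healthy)
    scores = rng.normal(mu, sigma)
    return scores, labels


def scenario_profile(name: str) -> ThresholdProfile:
    """One of the two bundled worked-example profiles.

    ``"prev25"``: 30 diseased / 90 healthy; cells (TN 36, FP 54, FN 6,
    TP 24). ``"prev75"``: 90 diseased / 30 healthy; cells (TN 12,
    FP 18, FN 18, TP 72). Both have a single cut-off c = 1 with
    SE = 0.8 and SP = 0.4.
    """
    if name not in _SCENARIOS:
        raise CutcostError(
            f"unknown scenario {name!r}; expected one of {sorted(_SCENARIOS)}"
        )
    return ThresholdProfile(thresholds=(1.0,), tables=(_SCENARIOS[name],))


def _realize(se: float, sp: float, n_dis: int, n_heal: int, c) -> ConfusionTable:
    tp = se * n_dis
    tn = sp * n_heal
    if abs(tp - round(tp)) > 1e-9 or abs(tn - round(tn)) > 1e-9:
        raise RealizabilityError(
            f"threshold c={c}: (se={se}, sp={sp}) implies non-integer cells "
            f"with {n_dis} diseased / {n_heal} healthy subjects"
        )
    tp, tn = int(round(tp)), int(round(tn))
    return ConfusionTable(tp=tp, fp=n_heal - tn, tn=tn, fn=n_dis - tp)


def matched_prevalence_pair(
    se_sp_rows: Sequence[tuple[float, float]],
    p1: float,
    p2: float,
    total: int,
) -> tuple[ThresholdProfile, ThresholdProfile]:
    """Two profiles with identical per-threshold (SE, SP) rows but
    different prevalences, realized as exact integer tables.

    Thresholds are the ordinals 1..k. Rows are realized exactly or not
    at all: non-integer implied cells raise a
    :class:`RealizabilityError` naming the threshold, never silently
    round. Across such a pair Youden's J and the log odds ratio agree
    row-wise by construction, while kappa at a fixed cost ratio
    generally differs — the two profiles answer the same (SE, SP)
    question with different implicit costs.
    """
    if not se_sp_rows:
        raise CutcostError("at least one (se, sp) row required")
    profiles = []
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise CutcostError(f"prevalence {p} must be strictly inside (0, 1)")
        n_dis = p * total
        if abs(n_dis - round(n_dis)) > 1e-9:
            raise RealizabilityError(
                f"prevalence {p} with total {total} implies a non-integer "
                "diseased count"
            )
        n_dis = int(round(n_dis))
        n_heal = total - n_dis
        tables = tuple(
            _realize(se, sp, n_dis, n_heal, c)
            for c, (se, sp) in enumerate(se_sp_rows, start=1)
        )
        profiles.append(
            ThresholdProfile(
                thresholds=tuple(float(c) for c in range(1, len(se_sp_rows) + 1)),
                tables=tables,
            )
        )
    return profiles[0], profiles[1]
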