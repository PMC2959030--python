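"""Empirical ROC curve and trapezoidal AUC.

The ROC curve is the locus of (1 - SP, SE) operating points traced as
the cut-off sweeps the observed scores under the score >= c positivity
rule — one interior point per distinct score, plus the (0, 0) endpoint
(cut-off above every score). The area under it equals the
Mann-Whitney probability that a random diseased subject outscores a
random healthy one, ties counting one half: the prevalence-free
"predictive utility" of a marker before any cost structure is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidTableError, UndefinedRateError

__all__ = ["RocCurve", "empirical_roc", "auc"]


@dataclass(frozen=True)
class RocCurve:
    """Ordered (1 - SP, SE) points from (0, 0) to (1, 1).

    ``thresholds`` holds the cut-off generating each point after the
    leading (0, 0) (NaN for that synthetic endpoint).
    """

    fpr: tuple
    tpr: tuple
    thresholds: tuple

    def __post_init__(self) -> None:
        f = np.asarray(self.fpr)
        t = np.asarray(self.tpr)
        if f.size != t.size or f.size < 2:
            raise InvalidTableError("curve needs matched fpr/tpr with >= 2 points")
        if (f[0], t[0]) != (0.0, 0.0) or (f[-1], t[-1]) != (1.0, 1.0):
            raise InvalidTableError("curve must run from (0, 0) to (1, 1)")
        if np.any(np.diff(f) < 0) or np.any(np.diff(t) < 0):
            raise InvalidTableError("fpr and tpr must be non-decreasing")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr, self.tpr))


def empirical_roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC of a continuous marker against binary labels.

    Cut-offs are the distinct observed scores, swept from high to low;
    the lowest score classifies everyone positive, closing the curve at
    (1, 1). Both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0 or s.shape != y.shape:
        raise InvalidTableError("scores and labels must be equal-length, non-empty")
    if not set(np.unique(y)) <= {0, 1}:
        raise InvalidTableError("labels must be binary 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0:
        raise UndefinedRateError("diseased margin is empty; SE undefined")
    if n0 == 0:
        raise UndefinedRateError("healthy margin is empty; SP undefined")
    # sort descending; the last index of each tied block gives the
    # cumulative (TP, FP) of the cut-off at that score value
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    block_end = np.nonzero(np.append(np.diff(s_sorted) != 0, True))[0]
    tps = np.cumsum(y_sorted)[block_end]
    fps = block_end + 1 - tps
    fpr = np.concatenate(([0.0], fps / n0))
    tpr = np.concatenate(([0.0], tps / n1))
    thresholds = np.concatenate(([np.nan], s_sorted[block_end]))
    return RocCurve(
        fpr=tuple(fpr.tolist()),
        tpr=tuple(tpr.tolist()),
        thresholds=tuple(thresholds.tolist()),
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under a ROC curve, in [0, 1]."""
    return float(np.trapezoid(np.asarray(curve.tpr), np.asarray(curve.fpr)))
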