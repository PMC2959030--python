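"""Shared fixtures and random-generation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from cutcost import (
    ConfusionTable,
    ThresholdProfile,
    profile_from_scores,
    scenario_profile,
    table_from_counts,
)


@pytest.fixture
def low_prev_table() -> ConfusionTable:
    """120-subject, 25%-prevalence worked-example table (SE .8, SP .4)."""
    return scenario_profile("prev25").tables[0]


@pytest.fixture
def high_prev_table() -> ConfusionTable:
    """120-subject, 75%-prevalence worked-example table (SE .8, SP .4)."""
    return scenario_profile("prev75").tables[0]


def random_table(rng: np.random.Generator, max_cell: int = 100) -> ConfusionTable:
    """A random count table with both margins non-empty."""
    while True:
        tp, fp, tn, fn = rng.integers(0, max_cell + 1, 4)
        if tp + fn > 0 and tn + fp > 0:
            return table_from_counts(int(tp), int(fp), int(tn), int(fn))


def random_profile(
    rng: np.random.Generator, n_thresholds: int = 5, n_subjects: int = 200
) -> ThresholdProfile:
    """A random monotone profile built by thresholding a binormal sample."""
    while True:
        labels = (rng.random(n_subjects) < rng.uniform(0.15, 0.85)).astype(int)
        if 0 < labels.sum() < n_subjects:
            break
    scores = rng.normal(labels * rng.uniform(0.2, 2.0), 1.0)
    qs = np.linspace(0.1, 0.9, n_thresholds)
    thresholds = np.unique(np.quantile(scores, qs))
    return profile_from_scores(scores, labels, thresholds)
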