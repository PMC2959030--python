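"""Delimited-text readers and writers for scores and threshold tables.

Two input dialects, both header-row delimited text with the delimiter
auto-detected from the extension (.tsv -> tab, otherwise comma):

* score files: columns ``score`` (float), ``label`` (0/1);
* threshold-table files: columns ``threshold``, ``tp``, ``fp``, ``tn``,
  ``fn`` (integer cells), one row per candidate cut-off.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import ConfusionTable, ThresholdProfile
from .exceptions import InvalidTableError

__all__ = ["read_scores", "read_threshold_tables", "write_profile"]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_scores(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a per-subject score/label file -> (scores, labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    missing = {"score", "label"} - set(df.columns)
    if missing:
        raise InvalidTableError(f"{path}: missing columns {sorted(missing)}")
    labels = df["label"].to_numpy()
    if not set(np.unique(labels)) <= {0, 1}:
        raise InvalidTableError(f"{path}: labels must be 0/1")
    return df["score"].to_numpy(dtype=float), labels.astype(int)


def read_threshold_tables(path: str | Path) -> ThresholdProfile:
    """Read pre-tabulated 2x2 tables at ordered cut-offs -> profile."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    missing = {"threshold", "tp", "fp", "tn", "fn"} - set(df.columns)
    if missing:
        raise InvalidTableError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("threshold")
    tables = tuple(
        ConfusionTable(tp=int(r.tp), fp=int(r.fp), tn=int(r.tn), fn=int(r.fn))
        for r in df.itertuples()
    )
    return ThresholdProfile(
        thresholds=tuple(df["threshold"].astype(float).tolist()), tables=tables
    )


def write_profile(profile: ThresholdProfile, path: str | Path) -> None:
    """Write a profile in the threshold-table dialect read back by
    :func:`read_threshold_tables`."""
    path = Path(path)
    rows = [
        {"threshold": c, "tp": t.tp, "fp": t.fp, "tn": t.tn, "fn": t.fn}
        for c, t in zip(profile.thresholds, profile.tables)
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)
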