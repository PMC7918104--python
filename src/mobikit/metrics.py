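"""Confusion-matrix statistics and grid aggregations.

Counts may be fractional: published summary tables report mean rates
over many classifier configurations, and the implied counts for a fixed
cohort are then non-integer.  All formulas accept that gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .errors import InputError

GRID_AXES = ("neurons", "epochs", "regularisation")


def _check_rate(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise InputError(f"{name}={value} outside [0, 1]")
    return float(value)


def youden(tpr: float, tnr: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    return _check_rate("tpr", tpr) + _check_rate("tnr", tnr) - 1.0


def counts_from_rates(tpr: float, tnr: float, n_pos: float, n_neg: float) -> dict:
    """Implied (possibly fractional) confusion counts for given class sizes."""
    _check_rate("tpr", tpr)
    _check_rate("tnr", tnr)
    if n_pos <= 0 or n_neg <= 0:
        raise InputError("class sizes must be positive")
    return {
        "tp": tpr * n_pos,
        "fn": (1.0 - tpr) * n_pos,
        "tn": tnr * n_neg,
        "fp": (1.0 - tnr) * n_neg,
    }


def accuracy(counts: dict) -> float:
    """(TP + TN) / total."""
    total = counts["tp"] + counts["fn"] + counts["tn"] + counts["fp"]
    if total <= 0:
        raise InputError("empty confusion matrix")
    if min(counts.values()) < 0:
        raise InputError("negative confusion count")
    return (counts["tp"] + counts["tn"]) / total


def mcc(counts: dict) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fn, tn, fp = counts["tp"], counts["fn"], counts["tn"], counts["fp"]
    if min(tp, fn, tn, fp) < 0:
        raise InputError("negative confusion count")
    if tp + fn + tn + fp <= 0:
        raise InputError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom <= 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class MetricsReport:
    """Classification rates plus the confusion counts they came from."""

    tpr: float
    tnr: float
    acc: float
    mcc: float
    j: float
    counts: dict = field(default_factory=dict)
    n_skipped_folds: int = 0

    @classmethod
    def from_counts(cls, counts: dict, n_skipped_folds: int = 0) -> "MetricsReport":
        tp, fn, tn, fp = counts["tp"], counts["fn"], counts["tn"], counts["fp"]
        tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
        tnr = tn / (tn + fp) if tn + fp > 0 else 0.0
        return cls(tpr=tpr, tnr=tnr, acc=accuracy(counts), mcc=mcc(counts),
                   j=tpr + tnr - 1.0, counts=dict(counts),
                   n_skipped_folds=n_skipped_folds)

    def as_dict(self) -> dict:
        return {"tpr": self.tpr, "tnr": self.tnr, "acc": self.acc,
                "mcc": self.mcc, "j": self.j, "counts": dict(self.counts),
                "n_skipped_folds": self.n_skipped_folds}


def report_from_rates(tpr: float, tnr: float, n_pos: float, n_neg: float) -> MetricsReport:
    """Full report implied by published mean rates and fixed class sizes."""
    return MetricsReport.from_counts(counts_from_rates(tpr, tnr, n_pos, n_neg))


def marginal_means(grid: Sequence[dict], axis: str,
                   rates: Iterable[str] = ("tpr", "tnr", "acc")) -> List[dict]:
    """Mean rates over the grid, collapsed onto one hyperparameter axis.

    ``grid`` rows are dicts with the hyperparameter keys ``neurons``,
    ``epochs``, ``regularisation`` plus rate entries.  ``axis='all'``
    averages the full grid into a single row.
    """
    grid = list(grid)
    if axis != "all" and axis not in GRID_AXES:
        raise InputError(f"unknown axis {axis!r}")
    if len(grid) != 18:
        raise InputError(f"expected the full 18-row grid, got {len(grid)} rows")
    if axis == "all":
        return [{r: float(np.mean([row[r] for row in grid])) for r in rates}]
    levels = sorted({row[axis] for row in grid}, key=lambda v: (isinstance(v, bool), v))
    out = []
    for level in levels:
        rows = [row for row in grid if row[axis] == level]
        entry = {axis: level}
        entry.update({r: float(np.mean([row[r] for row in rows])) for r in rates})
        out.append(entry)
    return out


def round_percent(x: float) -> int:
    """Half-up rounding to whole percent, as used in printed tables."""
    return int(np.floor(100.0 * x + 0.5))
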