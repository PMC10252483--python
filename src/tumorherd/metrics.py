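"""Confusion-count performance metrics and ROC/AUC.

The five headline metrics are computed from binary confusion counts as
percentages:

    AC  = (TP + TN) / (TP + TN + FP + FN) * 100
    PR  = TP / (TP + FP) * 100
    SE  = TP / (TP + FN) * 100
    SP  = TN / (TN + FP) * 100
    F1S = 2*TP / (2*TP + FP + FN) * 100

Values are held at full precision; displays round half-up to 4 decimals.
A metric whose denominator is zero is reported as undefined (None), never
as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricSet", "compute_metrics", "roc_auc",
           "metrics_table", "round4"]

_COLUMNS = ("AC", "PR", "SE", "SP", "F1S")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)


@dataclass(frozen=True)
class MetricSet:
    """The five derived percentages; None marks an undefined metric."""

    ac: float | None
    pr: float | None
    se: float | None
    sp: float | None
    f1s: float | None

    def rounded(self) -> dict[str, float | None]:
        return {k: (None if v is None else round4(v))
                for k, v in zip(_COLUMNS, (self.ac, self.pr, self.se, self.sp, self.f1s))}


def round4(value: float) -> float:
    """Half-up rounding at the 4th decimal, as printed in results tables."""
    return float(Decimal(repr(value)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity and F1 from counts."""
    return MetricSet(
        ac=_ratio(c.tp + c.tn, c.total),
        pr=_ratio(c.tp, c.tp + c.fp),
        se=_ratio(c.tp, c.tp + c.fn),
        sp=_ratio(c.tn, c.tn + c.fp),
        f1s=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def roc_auc(scores, labels) -> float:
    """Trapezoidal AUC of scores against binary labels (midrank for ties).

    The larger of the two label values is the positive class.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return float(roc_auc_score(y == classes[1], np.asarray(scores, dtype=float)))


def metrics_table(rows: list[tuple[str, ConfusionCounts]]) -> pd.DataFrame:
    """Per-row counts plus the five metrics, 4-decimal cells, blanks when
    undefined; row order preserved."""
    if not rows:
        raise ValueError("no rows")
    records = []
    for name, c in rows:
        rec = {"name": name, "TP": c.tp, "FN": c.fn, "TN": c.tn, "FP": c.fp}
        for col, v in compute_metrics(c).rounded().items():
            rec[col] = "" if v is None else f"{v:.4f}"
        records.append(rec)
    return pd.DataFrame.from_records(records)
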