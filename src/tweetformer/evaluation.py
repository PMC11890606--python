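"""Evaluation conventions for the tweet-classification tasks.

All binary tasks report precision, recall and F1 *for the positive class*;
the three-class drug-intake task reports the micro-averaged F1 over classes
1 and 2 (pool tp/fp/fn across those classes one-vs-rest, then take the
ratio once). Degenerate 0/0 ratios are defined as 0.0. Reported values are
rounded half-up to three decimals; rounding happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion",
    "precision_recall_f1",
    "micro_f1",
    "round_metric",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


def confusion(y_true: Sequence[int], y_pred: Sequence[int], positive_class: int) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else 0.0


def precision_recall_f1(c: ConfusionCounts) -> Metrics:
    """Positive-class precision/recall/F1 from counts; 0/0 -> 0.0."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return Metrics(precision=precision, recall=recall, f1=f1)


def micro_f1(y_true: Sequence[int], y_pred: Sequence[int], class_subset: Iterable[int]) -> float:
    """F1 from tp/fp/fn pooled over the classes in ``class_subset``."""
    subset = list(class_subset)
    if not subset:
        raise ValueError("class_subset must be non-empty")
    tp = fp = fn = 0
    for cls in subset:
        c = confusion(y_true, y_pred, cls)
        tp += c.tp
        fp += c.fp
        fn += c.fn
    return precision_recall_f1(ConfusionCounts(tp=tp, fp=fp, fn=fn)).f1


def round_metric(value: float, places: int = 3) -> float:
    """Half-up rounding used when printing metric values."""
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))
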