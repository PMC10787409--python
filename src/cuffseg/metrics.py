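"""Pixel-count evaluation: precision, IoU and Dice from pooled confusion tallies.

All three metrics derive from the same TP/FP/FN/TN pixel counts:

    Precision = TP / (TP + FP) * 100
    IoU       = TP / (TP + FP + FN) * 100
    Dice      = 2 TP / ((TP + FP) + (TP + FN)) * 100

Evaluation pools (sums) the counts over every pixel of every image before
applying the formulas once — the micro-average convention.  Under pooled
counts Dice and IoU are algebraically locked together,
``Dice = 2 IoU / (1 + IoU)``, which is the identity the table audit checks
on published result rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies; tp+fp+fn+tn equals the number of evaluated pixels."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two binary masks of identical shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator (no relevant pixels); "
                      f"reporting 0", stacklevel=3)
        return 0.0
    return 100.0 * num / den


def precision(c: ConfusionCounts) -> float:
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 100.0          # empty truth, empty prediction: perfect
    return _ratio(c.tp, c.tp + c.fp, "precision")


def iou(c: ConfusionCounts) -> float:
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 100.0
    return _ratio(c.tp, c.tp + c.fp + c.fn, "iou")


def dice(c: ConfusionCounts) -> float:
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 100.0
    return _ratio(2 * c.tp, (c.tp + c.fp) + (c.tp + c.fn), "dice")


def dice_from_iou(iou_pct: float) -> float:
    """Convert an IoU percentage to Dice via the shared-count identity.

    Rounded to 2 decimals, matching the precision of printed result tables.
    """
    if not (0.0 <= iou_pct <= 100.0):
        raise ValueError(f"iou percentage must be in [0, 100], got {iou_pct}")
    j = iou_pct / 100.0
    return round(100.0 * 2.0 * j / (1.0 + j), 2)


@dataclass(frozen=True)
class MetricsReport:
    """Precision/IoU/Dice (percent) plus the pooled counts behind them."""

    precision: float
    iou: float
    dice: float
    counts: ConfusionCounts

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricsReport":
        return cls(precision=precision(c), iou=iou(c), dice=dice(c), counts=c)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "iou": self.iou, "dice": self.dice,
            "tp": self.counts.tp, "fp": self.counts.fp,
            "fn": self.counts.fn, "tn": self.counts.tn,
        }


def evaluate_masks(pairs: Iterable[tuple[np.ndarray, np.ndarray]]
                   ) -> MetricsReport:
    """Pooled evaluation of (predicted, truth) mask pairs."""
    total = ConfusionCounts(0, 0, 0, 0)
    n = 0
    for pred, truth in pairs:
        total = total + confusion(pred, truth)
        n += 1
    if n == 0:
        raise DataError("cannot evaluate an empty dataset")
    return MetricsReport.from_counts(total)


def evaluate(model, dataset: Sequence, threshold: float = 0.5,
             per_image: bool = False):
    """Segment every sample and report pooled metrics.

    ``dataset`` holds objects with ``image``/``mask`` attributes (phantom
    samples) or plain (image, mask) tuples.  With ``per_image=True`` a
    DataFrame of per-image metrics is returned alongside the pooled report.
    """
    from .train import predict

    if len(dataset) == 0:
        raise DataError("cannot evaluate an empty dataset")
    total = ConfusionCounts(0, 0, 0, 0)
    rows = []
    for s in dataset:
        image, mask = (s.image, s.mask) if hasattr(s, "image") else s
        pred = predict(model, image, threshold)
        c = confusion(pred, mask)
        total = total + c
        if per_image:
            r = MetricsReport.from_counts(c)
            rows.append({"precision": r.precision, "iou": r.iou, "dice": r.dice})
    report = MetricsReport.from_counts(total)
    if per_image:
        return report, pd.DataFrame(rows)
    return report


# ---------------------------------------------------------------------------
# published-table audit
# ---------------------------------------------------------------------------

def load_reported_metrics() -> pd.DataFrame:
    """Published benchmark rows (model, table, pre, iou, dice) bundled as CSV."""
    with resources.files("cuffseg.data").joinpath(
            "reported_metrics.csv").open("r") as f:
        return pd.read_csv(f)


def audit_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check each reported row for pooled-count consistency.

    Adds ``dice_expected`` (from the printed IoU via the identity) and
    ``consistent`` (agreement with the printed Dice at its printed
    precision).  Inconsistent rows would indicate per-image averaging or a
    transcription problem; the bundled rows all pass.
    """
    df = (table if table is not None else load_reported_metrics()).copy()
    df["dice_expected"] = [dice_from_iou(v) for v in df["iou"]]
    # printed Dice may carry 1 or 2 decimals; compare at printed precision
    tol = [0.5 * 10.0 ** -_decimals(v) + 1e-9 for v in df["dice"]]
    df["consistent"] = np.abs(df["dice_expected"] - df["dice"]) <= tol
    return df


def _decimals(x: float) -> int:
    s = f"{x}"
    return len(s.split(".")[1]) if "." in s else 0
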