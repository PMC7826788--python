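"""Overlap metrics from pixel confusion counts.

Dice = 2 TP / ((TP+FP) + (TP+FN)), sensitivity = TP / (TP+FN) and
positive predictive value = TP / (TP+FP), with standard conventions for
the degenerate all-empty case. Fold-level aggregation reports the
arithmetic mean with the sample standard deviation (n-1 denominator),
formatted to three decimals as "m +/- s".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ValidationError

__all__ = ["ConfusionCounts", "MetricsResult", "confusion", "eq_metrics", "aggregate",
           "format_mean_std"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0  # tracked for completeness; the metrics never use it

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsResult:
    dice: float
    sensitivity: float
    ppv: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixelwise confusion counts between two binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise DimensionError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def eq_metrics(c: ConfusionCounts) -> MetricsResult:
    """Dice, sensitivity and PPV from confusion counts.

    Conventions for empty denominators: with TP = FP = FN = 0 (empty
    truth and empty prediction) all three metrics are 1; otherwise a
    metric whose own denominator is 0 is 0.
    """
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp == 0 and fp == 0 and fn == 0:
        return MetricsResult(1.0, 1.0, 1.0)
    dice = 2.0 * tp / ((tp + fp) + (tp + fn)) if (tp + fp + fn) else 1.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    return MetricsResult(dice, sens, ppv)


def aggregate(folds: list[MetricsResult]) -> dict[str, tuple[float, float]]:
    """Mean and sample std (ddof=1) per metric across folds.

    A single fold reports std 0. Raises on an empty list.
    """
    if not folds:
        raise ValidationError("aggregate requires at least one fold result")

    def stats(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=np.float64)
        std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), std

    return {
        "dice": stats([f.dice for f in folds]),
        "sensitivity": stats([f.sensitivity for f in folds]),
        "ppv": stats([f.ppv for f in folds]),
    }


def format_mean_std(mean: float, std: float, decimals: int = 3) -> str:
    """Render "0.982 ± 0.002"-style summaries."""
    return f"{mean:.{decimals}f} ± {std:.{decimals}f}"
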