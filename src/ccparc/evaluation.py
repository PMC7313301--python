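"""Per-parcel segmentation metrics and inter-method agreement tables.

Each parcel is evaluated one-vs-rest against ground truth via the pixelwise
confusion counts (TP, TN, FP, FN) and the five standard ratios:

    Dice        = 2 TP / (2 TP + FN + FP)
    Accuracy    = (TP + TN) / (TP + FN + TN + FP)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)

The evaluation domain is the full image by default (TN includes background);
``roi_only=True`` restricts counts to the union of the two maps' foregrounds.
A ratio with zero denominator is reported as NaN ("undefined"), except Dice
of two empty masks, which is defined as 1.0 (agreement on absence).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dice",
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "metric_report",
    "pairwise_dice_table",
]

logger = logging.getLogger(__name__)

METRICS = ("dice", "accuracy", "sensitivity", "specificity", "precision")
PARCELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _labels(m) -> np.ndarray:
    return np.asarray(m.labels if hasattr(m, "labels") else m)


def confusion(pred, truth, parcel: int, roi_only: bool = False) -> ConfusionCounts:
    """One-vs-rest pixel counts for one parcel label."""
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pp, tt = p == parcel, t == parcel
    if roi_only:
        dom = (p > 0) | (t > 0)
        pp, tt = pp[dom], tt[dom]
    return ConfusionCounts(
        tp=int(np.sum(pp & tt)),
        tn=int(np.sum(~pp & ~tt)),
        fp=int(np.sum(pp & ~tt)),
        fn=int(np.sum(~pp & tt)),
    )


def dice(c: ConfusionCounts) -> float:
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        logger.info("both masks empty for this parcel; Dice defined as 1.0")
        return 1.0
    return 2.0 * c.tp / (2.0 * c.tp + c.fn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else float("nan")


def sensitivity(c: ConfusionCounts) -> float:
    d = c.tp + c.fn
    return c.tp / d if d else float("nan")


def specificity(c: ConfusionCounts) -> float:
    d = c.tn + c.fp
    return c.tn / d if d else float("nan")


def precision(c: ConfusionCounts) -> float:
    d = c.tp + c.fp
    return c.tp / d if d else float("nan")


_FUNCS = {
    "dice": dice,
    "accuracy": accuracy,
    "sensitivity": sensitivity,
    "specificity": specificity,
    "precision": precision,
}


def metric_report(pred, truth, roi_only: bool = False) -> pd.DataFrame:
    """Five metrics per parcel plus mean and standard-deviation rows."""
    rows = {}
    for parcel in PARCELS:
        c = confusion(pred, truth, parcel, roi_only=roi_only)
        rows[f"parcel {parcel}"] = {name: _FUNCS[name](c) for name in METRICS}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRICS))
    df.loc["mean"] = df.loc[[f"parcel {p}" for p in PARCELS]].mean()
    df.loc["std"] = df.loc[[f"parcel {p}" for p in PARCELS]].std()
    return df


def pairwise_dice_table(maps: dict, roi_only: bool = False) -> pd.DataFrame:
    """Per-parcel Dice for every unordered pair of named parcel maps."""
    names = list(maps)
    if len(names) < 2:
        raise ValueError("need at least 2 maps for a pairwise table")
    shapes = {n: _labels(m).shape for n, m in maps.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"maps have differing shapes: {shapes}")
    table = {}
    for a, b in itertools.combinations(names, 2):
        col = f"{a} vs {b}"
        table[col] = [
            dice(confusion(maps[a], maps[b], parcel, roi_only=roi_only))
            for parcel in PARCELS
        ]
    return pd.DataFrame(table, index=[f"parcel {p}" for p in PARCELS])
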