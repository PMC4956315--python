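"""Pixel-wise segmentation metrics against manual ground truth.

Acc = (TP+TN)/(TP+FP+TN+FN), Sn = TP/(TP+FN), Sp = TN/(TN+FP), and the
AUC summary (Sn+Sp)/2 — a single-operating-point summary, not an
integrated ROC sweep.  Counts are tallied inside the field-of-view mask
when one is given, else over the full frame, and each record carries
which region was used so the two modes are never silently mixed (a known
source of accuracy variation between publications).

Metric arithmetic runs in exact integer fractions before conversion to
float, so report rounding (half away from zero, 3 decimals per image and
5 for dataset averages) reproduces printed table values without binary
round-off surprises.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "UndefinedMetricError",
    "confusion_counts",
    "compute_metrics",
    "aggregate",
    "round_metric",
    "records_to_frame",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (no positives, or no negatives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies over the evaluated region."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsRecord:
    """Per-image (or averaged) accuracy, sensitivity, specificity and AUC."""

    image_id: str
    acc: float
    sn: float
    sp: float
    auc: float
    eval_region: str = "full"


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between a predicted and a manual binary mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    p = pred > 0
    t = truth > 0
    if fov is not None:
        fov = np.asarray(fov)
        if fov.shape != pred.shape:
            raise ValueError(f"fov shape {fov.shape} does not match {pred.shape}")
        sel = fov > 0
        if not sel.any():
            raise ValueError("empty field-of-view mask")
        p, t = p[sel], t[sel]
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(
    c: ConfusionCounts, image_id: str = "", eval_region: str = "full"
) -> MetricsRecord:
    """Acc, Sn, Sp and AUC = (Sn+Sp)/2 from confusion counts."""
    if c.total == 0:
        raise UndefinedMetricError("no pixels were evaluated")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive pixels")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative pixels")
    acc = Fraction(c.tp + c.tn, c.total)
    sn = Fraction(c.tp, c.tp + c.fn)
    sp = Fraction(c.tn, c.tn + c.fp)
    auc = (sn + sp) / 2
    return MetricsRecord(
        image_id=image_id,
        acc=float(acc),
        sn=float(sn),
        sp=float(sp),
        auc=float(auc),
        eval_region=eval_region,
    )


def aggregate(records: Sequence[MetricsRecord]) -> MetricsRecord:
    """Unweighted dataset average: mean Acc/Sn/Sp, AUC recomputed from them."""
    records = list(records)
    if not records:
        raise ValueError("cannot aggregate an empty list of records")
    regions = {r.eval_region for r in records}
    if len(regions) > 1:
        raise ValueError(f"mixed evaluation regions {sorted(regions)}")
    n = len(records)
    acc = sum(r.acc for r in records) / n
    sn = sum(r.sn for r in records) / n
    sp = sum(r.sp for r in records) / n
    return MetricsRecord(
        image_id="average",
        acc=acc,
        sn=sn,
        sp=sp,
        auc=(sn + sp) / 2,
        eval_region=records[0].eval_region,
    )


def round_metric(value: float, ndigits: int = 3) -> float:
    """Round half away from zero at *ndigits* decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def records_to_frame(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    """Tabulate records with columns image_id, acc, sn, sp, auc, eval_region."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "acc": r.acc,
                "sn": r.sn,
                "sp": r.sp,
                "auc": r.auc,
                "eval_region": r.eval_region,
            }
            for r in records
        ]
    )
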