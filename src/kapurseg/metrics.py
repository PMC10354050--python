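"""Pixelwise confusion counts and binary segmentation quality measures.

Lesion pixels are the positive class.  Eight measures are reported:
accuracy, sensitivity (recall), specificity, precision, geometric mean
GM = sqrt(sens * spec), F1, false-positive rate FPR = 1 - specificity,
and the Dice similarity coefficient DSC = 2TP / (2TP + FP + FN).  For
binary masks DSC and F1 are algebraically identical.

A measure whose denominator is zero (e.g. sensitivity with an empty
ground truth) is reported as NaN rather than silently 0; aggregation
helpers skip NaNs and report how many values were skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "gm", "f1", "fpr", "dsc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    gm: float
    f1: float
    fpr: float
    dsc: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Four pixel categories of a predicted vs ground-truth lesion mask."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth must share a shape")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All eight measures from confusion counts; undefined ones are NaN."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    gm = math.sqrt(sens * spec) if not (math.isnan(sens) or math.isnan(spec)) else float("nan")
    f1 = _ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)
    fpr = _ratio(c.fp, c.fp + c.tn)
    dsc = _ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         precision=prec, gm=gm, f1=f1, fpr=fpr, dsc=dsc)


def evaluate_masks(pred_mask: np.ndarray, gt_mask: np.ndarray) -> MetricsReport:
    """Convenience: confusion counts then metrics in one call."""
    return compute_metrics(confusion(pred_mask, gt_mask))


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean/std per metric across reports, skipping NaN (flagged) values.

    Returns ``{metric: {"mean": m, "std": s, "n_skipped": k}}``.
    """
    out: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        ok = vals[~np.isnan(vals)]
        out[name] = {
            "mean": float(ok.mean()) if ok.size else float("nan"),
            "std": float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
            "n_skipped": int(np.isnan(vals).sum()),
        }
    return out
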