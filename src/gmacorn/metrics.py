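"""Detection metrics (precision/recall/AP/mAP) and field-trial delivery
metrics with trial aggregation.

Field metrics follow the standard triple: delivery rate = N_success/N_total,
detection accuracy = N_identified/N_total, delivery precision =
N_success/N_identified — so rate = accuracy × precision holds exactly on
the unrounded ratios.  Percentages are rounded half-up to one decimal;
group summaries report mean ± sample (n−1) standard deviation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .assign import iou as _box_iou

__all__ = ["ConfusionCounts", "FieldTrialCounts", "TrialSummary",
           "precision_recall", "average_precision", "map50",
           "delivery_metrics", "summarize_trials", "read_counts_csv",
           "evaluate_detections"]


def _round1(x: float) -> float:
    """Half-up rounding to one decimal (the table-printing convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class FieldTrialCounts:
    n_total: int
    n_identified: int
    n_success: int

    def __post_init__(self):
        if not (0 <= self.n_success <= self.n_identified <= self.n_total):
            raise ValueError(
                "counts must satisfy n_success <= n_identified <= n_total")


@dataclass(frozen=True)
class TrialSummary:
    per_group: tuple      # unrounded per-group values (%)
    mean: float           # rounded to one decimal
    sd: float             # sample SD, rounded to one decimal


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators yield 0 with a
    warning."""
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (TP+FP=0); returning 0")
        p = 0.0
    else:
        p = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (TP+FN=0); returning 0")
        r = 0.0
    else:
        r = c.tp / (c.tp + c.fn)
    return p, r


def average_precision(detections, gts, iou_threshold: float = 0.5) -> float:
    """AP from ranked detections against ground truth boxes.

    ``detections``: iterable of (confidence, image_id, box_xyxy); ``gts``:
    iterable of (image_id, box_xyxy).  Matching is greedy in confidence
    order (ties broken by detection index): a detection is a TP if its best
    unmatched same-image GT reaches the IoU threshold.  The PR curve is
    integrated with the all-point interpolated (precision-envelope) rule.
    """
    gts = list(gts)
    n_gt = len(gts)
    if n_gt == 0:
        raise ValueError("average precision undefined without ground truth")
    dets = sorted(enumerate(detections), key=lambda kv: (-kv[1][0], kv[0]))
    matched = [False] * n_gt
    tps = []
    for _, (conf, img, box) in dets:
        best, best_iou = -1, iou_threshold
        for j, (gimg, gbox) in enumerate(gts):
            if gimg != img or matched[j]:
                continue
            v = _box_iou(box, gbox)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            matched[best] = True
            tps.append(1)
        else:
            tps.append(0)
    tp = np.cumsum(tps)
    fp = np.cumsum([1 - t for t in tps])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope + step integration over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map50(per_class_aps) -> float:
    """Arithmetic mean of per-class APs at IoU 0.5."""
    aps = list(per_class_aps)
    if not aps:
        raise ValueError("mAP undefined for zero classes")
    return float(np.mean(aps))


def delivery_metrics(c: FieldTrialCounts,
                     rounded: bool = True) -> tuple[float, float, float]:
    """(delivery rate %, detection accuracy %, delivery precision %).

    The second value is the field instantiation of the "correct / total
    leaf areas" accuracy: identified plants over total plants.
    """
    if c.n_identified == 0:
        raise ValueError("delivery precision undefined (n_identified = 0)")
    rate = 100.0 * c.n_success / c.n_total
    acc = 100.0 * c.n_identified / c.n_total
    prec = 100.0 * c.n_success / c.n_identified
    if rounded:
        return _round1(rate), _round1(acc), _round1(prec)
    return rate, acc, prec


# alias reflecting the "N_correct / N_leaf" naming of the accuracy ratio
def detection_accuracy(n_correct: int, n_leaf: int) -> float:
    return _round1(100.0 * n_correct / n_leaf)


def summarize_trials(groups) -> dict[str, TrialSummary]:
    """Per-metric mean ± sample SD over trial groups.

    Group values are first rounded to one decimal (the precision at which
    trial tables are printed) and the mean and sample (n−1) SD are taken
    over those printed values — the convention that reproduces published
    trial summaries exactly.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a standard deviation")
    vals = np.array([delivery_metrics(g, rounded=True) for g in groups])
    names = ("delivery_rate", "detection_accuracy", "delivery_precision")
    out = {}
    for j, name in enumerate(names):
        col = vals[:, j]
        out[name] = TrialSummary(tuple(col), _round1(col.mean()),
                                 _round1(col.std(ddof=1)))
    return out


def read_counts_csv(path) -> list[FieldTrialCounts]:
    """CSV columns: group, n_total, n_identified, n_success (header row
    optional)."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh):
            if not rec or not rec[-1].strip().isdigit():
                continue
            vals = [int(v) for v in rec[-3:]]
            rows.append(FieldTrialCounts(*vals))
    return rows


def evaluate_detections(pred_by_image: dict, gt_by_image: dict,
                        iou_threshold: float = 0.5) -> dict:
    """Single-class evaluation of prediction dicts.

    ``pred_by_image``: image_id -> list of (conf, box_xyxy);
    ``gt_by_image``: image_id -> list of box_xyxy.
    """
    dets = [(conf, img, box) for img, lst in pred_by_image.items()
            for conf, box in lst]
    gts = [(img, box) for img, lst in gt_by_image.items() for box in lst]
    ap = average_precision(dets, gts, iou_threshold)
    return {"ap50": ap, "map50": map50([ap]), "n_detections": len(dets),
            "n_gt": len(gts)}
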