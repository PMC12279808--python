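"""Label assignment for anchor-free detection training.

Three assigners are provided:

* :func:`assign_lead` — task-aligned assignment (alignment metric
  ``score^α · IoU^β``, top-k candidates restricted to anchors whose center
  lies inside the ground-truth box) producing fine soft targets for the
  deployed lead head.
* :func:`assign_aux` — the relaxed coarse variant for the auxiliary head:
  the candidate region is the ground-truth box enlarged by a factor of two
  around its center and top-k is doubled.  Its positive set is by
  construction a superset of the lead positives for the same frame.
* :func:`simota_assign` — SimOTA: IoU-derived dynamic-k selection of the
  lowest-cost candidates per ground truth, available as an alternative
  assigner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AssignmentResult", "iou", "iou_matrix", "simota_assign",
           "assign_lead", "assign_aux", "cxcywh_to_xyxy"]


def cxcywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64)
    cx, cy, w, h = boxes[..., 0], boxes[..., 1], boxes[..., 2], boxes[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def iou(box_a, box_b, fmt: str = "xyxy") -> float:
    """Intersection-over-union of two boxes."""
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    if fmt == "cxcywh":
        a, b = cxcywh_to_xyxy(a), cxcywh_to_xyxy(b)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    if area_a <= 0 or area_b <= 0:
        raise ValueError("zero-area box")
    iw = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    ih = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (G,4) and (A,4) xyxy arrays -> (G, A)."""
    a = np.asarray(a, dtype=np.float64)[:, None, :]
    b = np.asarray(b, dtype=np.float64)[None, :, :]
    iw = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]),
                 0, None)
    ih = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]),
                 0, None)
    inter = iw * ih
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    return inter / np.maximum(area_a + area_b - inter, 1e-12)


@dataclass
class AssignmentResult:
    """Per-anchor assignment: matched GT index (-1 = background), positive
    mask and soft target scores (n_anchors, n_classes)."""

    gt_index: np.ndarray
    positive: np.ndarray
    target_scores: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())


def simota_assign(costs: np.ndarray, ious: np.ndarray,
                  topq: int = 10) -> AssignmentResult:
    """SimOTA dynamic-k assignment.

    ``dynamic_k`` per GT is ``clamp(round(sum of top-q IoUs), 1, n_cand)``;
    each GT claims its k lowest-cost candidates and a candidate claimed by
    several GTs keeps only its lowest-cost match.
    """
    costs = np.asarray(costs, dtype=np.float64)
    ious = np.asarray(ious, dtype=np.float64)
    if costs.size == 0:
        n = costs.shape[1] if costs.ndim == 2 else 0
        return AssignmentResult(np.full(n, -1), np.zeros(n, bool),
                                np.zeros((n, 1)))
    if np.any(costs < 0):
        raise ValueError("cost matrix must be non-negative")
    n_gt, n_cand = costs.shape
    claimed = np.full(n_cand, -1, dtype=np.int64)
    claim_cost = np.full(n_cand, np.inf)
    for g in range(n_gt):
        q = min(topq, n_cand)
        topq_ious = np.sort(ious[g])[::-1][:q]
        k = int(np.clip(round(float(topq_ious.sum())), 1, n_cand))
        picks = np.argsort(costs[g], kind="stable")[:k]
        for c in picks:
            if costs[g, c] < claim_cost[c]:
                claim_cost[c] = costs[g, c]
                claimed[c] = g
    positive = claimed >= 0
    scores = np.zeros((n_cand, 1))
    scores[positive, 0] = ious[claimed[positive], np.where(positive)[0]]
    return AssignmentResult(claimed, positive, scores)


def _task_aligned(scores: np.ndarray, pred_boxes: np.ndarray,
                  anchor_points: np.ndarray, gt_boxes: np.ndarray,
                  gt_classes: np.ndarray, topk: int, alpha: float,
                  beta: float, center_factor: float,
                  num_classes: int) -> AssignmentResult:
    n_anchor = anchor_points.shape[0]
    gt_index = np.full(n_anchor, -1, dtype=np.int64)
    target = np.zeros((n_anchor, num_classes))
    if len(gt_boxes) == 0:
        return AssignmentResult(gt_index, np.zeros(n_anchor, bool), target)

    gt = np.asarray(gt_boxes, dtype=np.float64)
    cx = (gt[:, 0] + gt[:, 2]) / 2
    cy = (gt[:, 1] + gt[:, 3]) / 2
    hw = (gt[:, 2] - gt[:, 0]) / 2 * center_factor
    hh = (gt[:, 3] - gt[:, 1]) / 2 * center_factor
    px, py = anchor_points[:, 0], anchor_points[:, 1]
    in_box = ((px[None] >= (cx - hw)[:, None]) & (px[None] <= (cx + hw)[:, None])
              & (py[None] >= (cy - hh)[:, None]) & (py[None] <= (cy + hh)[:, None]))

    ious = iou_matrix(gt, pred_boxes)
    cls_scores = scores[:, gt_classes].T            # (G, A)
    metric = (cls_scores ** alpha) * (ious ** beta)
    metric = np.where(in_box, metric, 0.0)

    # top-k per GT among its candidates
    cand = np.zeros_like(in_box)
    for g in range(len(gt)):
        order = np.argsort(-metric[g], kind="stable")[:topk]
        order = order[metric[g, order] > 0]
        # fall back to the nearest in-box anchor if all metrics vanish
        if order.size == 0 and in_box[g].any():
            d2 = (px - cx[g]) ** 2 + (py - cy[g]) ** 2
            d2 = np.where(in_box[g], d2, np.inf)
            order = np.array([int(np.argmin(d2))])
        cand[g, order] = True

    # conflict resolution: anchor keeps the GT with the highest metric
    best_gt = np.argmax(np.where(cand, metric, -1.0), axis=0)
    positive = cand.any(axis=0)
    gt_index[positive] = best_gt[positive]

    # normalized soft target scores (task-aligned normalization)
    for g in range(len(gt)):
        mask = positive & (gt_index == g)
        if not mask.any():
            continue
        mm = metric[g, mask]
        denom = mm.max() + 1e-9
        target[mask, gt_classes[g]] = mm / denom * ious[g, mask].max()
    return AssignmentResult(gt_index, positive, target)


def assign_lead(scores, pred_boxes, anchor_points, gt_boxes, gt_classes,
                topk: int = 10, alpha: float = 0.5, beta: float = 6.0,
                num_classes: int = 1) -> AssignmentResult:
    """Fine-grained task-aligned assignment for the lead head."""
    return _task_aligned(np.asarray(scores, dtype=np.float64),
                         np.asarray(pred_boxes, dtype=np.float64),
                         np.asarray(anchor_points, dtype=np.float64),
                         gt_boxes, np.asarray(gt_classes, dtype=np.int64),
                         topk, alpha, beta, 1.0, num_classes)


def assign_aux(scores, pred_boxes, anchor_points, gt_boxes, gt_classes,
               topk: int = 10, alpha: float = 0.5, beta: float = 6.0,
               num_classes: int = 1) -> AssignmentResult:
    """Coarse assignment for the auxiliary head.

    Runs the relaxed assigner (candidate region enlarged 2x, top-k doubled)
    and unions its positives with the lead assignment, so the auxiliary
    positive set always contains the lead positives.
    """
    lead = assign_lead(scores, pred_boxes, anchor_points, gt_boxes,
                       gt_classes, topk, alpha, beta, num_classes)
    relaxed = _task_aligned(np.asarray(scores, dtype=np.float64),
                            np.asarray(pred_boxes, dtype=np.float64),
                            np.asarray(anchor_points, dtype=np.float64),
                            gt_boxes, np.asarray(gt_classes, dtype=np.int64),
                            2 * topk, alpha, beta, 2.0, num_classes)
    gt_index = relaxed.gt_index.copy()
    positive = relaxed.positive | lead.positive
    # lead cores keep their fine mapping; extra cells keep the coarse one
    gt_index[lead.positive] = lead.gt_index[lead.positive]
    target = np.maximum(relaxed.target_scores, lead.target_scores)
    return AssignmentResult(gt_index, positive, target)
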