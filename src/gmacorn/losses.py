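"""Detection training loss: BCE classification + CIoU + distribution-focal
box regression over task-aligned assignments."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, no_grad, stable_sigmoid
from .blocks import make_anchors
from .assign import assign_aux, assign_lead

__all__ = ["DetectionLoss"]

_EPS = 1e-7


def _tmin(a: Tensor, b: Tensor) -> Tensor:
    return a - (a - b).clamp(0, None)


def _tmax(a: Tensor, b: Tensor) -> Tensor:
    return a + (b - a).clamp(0, None)


def _ciou(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Complete IoU between predicted boxes (P,4 xyxy, Tensor) and ground
    truth (P,4 xyxy, ndarray)."""
    g = Tensor(gt.astype(np.float32))
    ix1 = _tmax(pred[:, 0], g[:, 0])
    iy1 = _tmax(pred[:, 1], g[:, 1])
    ix2 = _tmin(pred[:, 2], g[:, 2])
    iy2 = _tmin(pred[:, 3], g[:, 3])
    iw = (ix2 - ix1).clamp(0, None)
    ih = (iy2 - iy1).clamp(0, None)
    inter = iw * ih
    pw = (pred[:, 2] - pred[:, 0]).clamp(_EPS, None)
    ph = (pred[:, 3] - pred[:, 1]).clamp(_EPS, None)
    gw = g[:, 2] - g[:, 0]
    gh = g[:, 3] - g[:, 1]
    union = pw * ph + gw * gh - inter + _EPS
    iou = inter / union
    # enclosing box diagonal
    cw = _tmax(pred[:, 2], g[:, 2]) - _tmin(pred[:, 0], g[:, 0])
    ch = _tmax(pred[:, 3], g[:, 3]) - _tmin(pred[:, 1], g[:, 1])
    c2 = cw * cw + ch * ch + _EPS
    rho2 = ((pred[:, 0] + pred[:, 2] - g[:, 0] - g[:, 2]) ** 2
            + (pred[:, 1] + pred[:, 3] - g[:, 1] - g[:, 3]) ** 2) * 0.25
    v = (4.0 / np.pi ** 2) * ((gw / gh).arctan() - (pw / ph).arctan()) ** 2
    with no_grad():
        alpha = v.data / (1.0 - iou.data + v.data + _EPS)
    return iou - rho2 / c2 - Tensor(alpha) * v


def _bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    p = logits.sigmoid().clamp(_EPS, 1.0 - _EPS)
    t = Tensor(targets.astype(np.float32))
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log())


class DetectionLoss:
    """YOLOv8-style loss over multi-scale raw head outputs.

    Gains: 7.5 (CIoU box), 0.5 (BCE class), 1.5 (DFL).  The auxiliary head
    is scored with the coarse assigner and weighted by ``aux_weight``.
    """

    def __init__(self, num_classes: int = 1, reg_max: int = 16,
                 strides=(8, 16, 32), box_gain=7.5, cls_gain=0.5,
                 dfl_gain=1.5, aux_weight=0.25):
        self.nc, self.reg_max = num_classes, reg_max
        self.strides = strides
        self.gains = (box_gain, cls_gain, dfl_gain)
        self.aux_weight = aux_weight

    # -- helpers ---------------------------------------------------------
    def _flatten(self, maps):
        """maps: list of (N, 4*reg_max+nc, H, W) -> dist (N,A,4,R), cls (N,A,nc)."""
        shapes = [(m.shape[2], m.shape[3]) for m in maps]
        flat = []
        for m in maps:
            n, c, h, w = m.shape
            flat.append(m.reshape(n, c, h * w).transpose(0, 2, 1))
        x = concat(flat, axis=1)                     # (N, A, C)
        r4 = 4 * self.reg_max
        dist = x[:, :, :r4].reshape(x.shape[0], x.shape[1], 4, self.reg_max)
        cls = x[:, :, r4:]
        return dist, cls, shapes

    def _decode(self, dist: Tensor, points: np.ndarray, strides: np.ndarray):
        """Distribution -> expected ltrb distances -> xyxy boxes (pixels)."""
        prob = dist.softmax(axis=-1)
        bins = Tensor(np.arange(self.reg_max, dtype=np.float32))
        ltrb = (prob * bins).sum(axis=-1)            # (N, A, 4) grid units
        s = Tensor(strides.astype(np.float32).reshape(1, -1, 1))
        ltrb_px = ltrb * s
        p = Tensor(points.astype(np.float32)[None])  # (1, A, 2)
        x1 = p[:, :, 0] - ltrb_px[:, :, 0]
        y1 = p[:, :, 1] - ltrb_px[:, :, 1]
        x2 = p[:, :, 0] + ltrb_px[:, :, 2]
        y2 = p[:, :, 1] + ltrb_px[:, :, 3]
        boxes = concat([x1.reshape(*x1.shape, 1), y1.reshape(*y1.shape, 1),
                        x2.reshape(*x2.shape, 1), y2.reshape(*y2.shape, 1)],
                       axis=2)
        return boxes, prob

    def _head_loss(self, maps, targets, assigner):
        dist, cls, shapes = self._flatten(maps)
        points, strides = make_anchors(shapes, self.strides)
        boxes, prob = self._decode(dist, points, strides)
        n, a = cls.shape[0], cls.shape[1]

        tgt_scores = np.zeros((n, a, self.nc), dtype=np.float32)
        pos_bi, pos_ai, pos_gt_boxes, pos_weight = [], [], [], []
        with no_grad():
            scores_np = stable_sigmoid(cls.data)
            boxes_np = boxes.data
        for i, (gt_cls, gt_boxes) in enumerate(targets):
            gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
            gt_cls = np.asarray(gt_cls, dtype=np.int64).reshape(-1)
            res = assigner(scores_np[i], boxes_np[i], points, gt_boxes,
                           gt_cls, num_classes=self.nc)
            tgt_scores[i] = res.target_scores
            idx = np.where(res.positive)[0]
            if idx.size:
                pos_bi.append(np.full(idx.size, i))
                pos_ai.append(idx)
                pos_gt_boxes.append(gt_boxes[res.gt_index[idx]])
                pos_weight.append(res.target_scores[idx].sum(axis=1))

        score_sum = max(float(tgt_scores.sum()), 1.0)
        loss_cls = _bce(cls, tgt_scores).sum() * (1.0 / score_sum)

        if pos_bi:
            bi = np.concatenate(pos_bi)
            ai = np.concatenate(pos_ai)
            gtb = np.concatenate(pos_gt_boxes).astype(np.float32)
            w = Tensor(np.concatenate(pos_weight).astype(np.float32))
            pb = boxes[(bi, ai)]                     # (P, 4)
            ciou = _ciou(pb, gtb)
            loss_box = ((1.0 - ciou) * w).sum() * (1.0 / score_sum)
            # DFL on stride-normalized ltrb targets
            st = strides[ai].astype(np.float64)
            pts = points[ai]
            lt = np.stack([(pts[:, 0] - gtb[:, 0]) / st,
                           (pts[:, 1] - gtb[:, 1]) / st], axis=1)
            rb = np.stack([(gtb[:, 2] - pts[:, 0]) / st,
                           (gtb[:, 3] - pts[:, 1]) / st], axis=1)
            tgt = np.clip(np.concatenate([lt, rb], axis=1), 0,
                          self.reg_max - 1 - 0.01)  # (P, 4)
            tl = np.floor(tgt).astype(np.int64)
            tr = tl + 1
            wl = (tr - tgt).astype(np.float32)
            wr = 1.0 - wl
            pprob = prob[(bi, ai)].clamp(_EPS, None)  # (P, 4, R)
            pi = np.arange(len(bi))[:, None]
            fi = np.arange(4)[None, :]
            nll = -(pprob[(pi, fi, tl)].log() * Tensor(wl)
                    + pprob[(pi, fi, tr)].log() * Tensor(wr))
            loss_dfl = (nll.mean(axis=1) * w).sum() * (1.0 / score_sum)
        else:
            loss_box = Tensor(np.zeros(()))
            loss_dfl = Tensor(np.zeros(()))

        bg, cg, dg = self.gains
        return loss_box * bg + loss_cls * cg + loss_dfl * dg

    def __call__(self, outputs: dict, targets) -> Tensor:
        """``outputs`` is the model forward dict; ``targets`` is a list of
        (gt_classes, gt_boxes_xyxy_pixels) per image."""
        total = self._head_loss(outputs["lead"], targets, assign_lead)
        if "aux" in outputs:
            total = total + self._head_loss(outputs["aux"], targets,
                                            assign_aux) * self.aux_weight
        return total
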