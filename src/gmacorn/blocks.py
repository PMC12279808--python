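"""Composite detector blocks shared by the baseline and GMA variants."""

from __future__ import annotations

import numpy as np

from .attention import GhostConv, MLCA
from .autograd import Tensor, concat
from .layers import Conv, Conv2d, Module, ModuleList, Sequential

__all__ = ["Bottleneck", "C2f", "CM", "GhostHGBlock", "Detect"]


class Bottleneck(Module):
    """Two 3x3 convs with optional residual; optionally MLCA-gated (CM)."""

    def __init__(self, c1, c2, shortcut=True, e=0.5, with_mlca=False):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 3, 1)
        self.cv2 = Conv(c_, c2, 3, 1)
        self.add = shortcut and c1 == c2
        self.mlca = MLCA(c2) if with_mlca else None

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        if self.mlca is not None:
            y = self.mlca(y)
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage partial block with n bottlenecks (YOLOv8 style)."""

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5, with_mlca=False):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, 1)
        self.m = ModuleList([
            Bottleneck(self.c, self.c, shortcut, e=1.0, with_mlca=with_mlca)
            for _ in range(n)
        ])

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, :self.c], y[:, self.c:]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))


class CM(C2f):
    """C2f variant whose bottlenecks each carry an MLCA gate."""

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5):
        super().__init__(c1, c2, n, shortcut, e, with_mlca=True)


class GhostHGBlock(Module):
    """HGNetV2 block with its dense 3x3 convs replaced by GhostConv (s=2).

    n successive ghost convolutions are applied, every intermediate output
    is concatenated with the block input, and a 1x1 squeeze + 1x1 excite
    pair fuses the stack; a residual connection is kept when shapes allow.
    """

    def __init__(self, c1, cm, c2, k=3, n=3, shortcut=True, ratio=2):
        super().__init__()
        self.m = ModuleList([
            GhostConv(c1 if i == 0 else cm, cm, k, 1, ratio) for i in range(n)
        ])
        self.sc = Conv(c1 + n * cm, c2 // 2, 1, 1)
        self.ec = Conv(c2 // 2, c2, 1, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        ys = [x]
        for m in self.m:
            ys.append(m(ys[-1]))
        y = self.ec(self.sc(concat(ys, axis=1)))
        return x + y if self.add else y


class Detect(Module):
    """Anchor-free decoupled detection head over three feature scales.

    Each scale emits ``4*reg_max`` box-distribution channels and ``nc``
    class channels.  Box decoding (distribution expectation) is done by the
    loss / predictor, not here.
    """

    def __init__(self, nc: int, ch: tuple[int, ...], reg_max: int = 16,
                 strides: tuple[int, ...] = (8, 16, 32)):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        self.strides = strides
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_branch = ModuleList([
            Sequential(Conv(c, c2, 3), Conv(c2, c2, 3),
                       Conv2d(c2, 4 * reg_max, 1)) for c in ch
        ])
        self.cls_branch = ModuleList([
            Sequential(Conv(c, c3, 3), Conv(c3, c3, 3),
                       Conv2d(c3, nc, 1)) for c in ch
        ])

    def forward(self, feats):
        return [
            concat([self.box_branch[i](f), self.cls_branch[i](f)], axis=1)
            for i, f in enumerate(feats)
        ]


def make_anchors(shapes, strides, offset=0.5):
    """Anchor-point centers (in pixels) and per-anchor stride for a set of
    feature-map shapes ``[(h, w), ...]``."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts.append(np.stack([(xx.ravel() + offset) * s,
                             (yy.ravel() + offset) * s], axis=1))
        strs.append(np.full((h * w,), s, dtype=np.float64))
    return np.concatenate(pts, axis=0), np.concatenate(strs, axis=0)
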