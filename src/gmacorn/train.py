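"""Smoke-scale training loop: SGD with momentum over synthetic scenes.

This is deliberately small-scale machinery — enough to demonstrate that the
full pipeline (architecture → assignment → loss → gradients) optimizes, not
a production trainer.  Default hyperparameters follow the usual YOLO
recipe: SGD, lr0 0.01, momentum 0.937, weight decay 0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .autograd import Tensor
from .losses import DetectionLoss

__all__ = ["TrainConfig", "SGD", "train_smoke"]


@dataclass
class TrainConfig:
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    epochs: int = 300
    imgsz: int = 640
    iou: float = 0.7
    batch_size: int = 4

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=0.0005):
        self.params = list(params)
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            v *= self.mu
            v -= self.lr * g
            p.data += v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _to_targets(labels: np.ndarray, imgsz: int):
    """YOLO-normalized (cls, cx, cy, w, h) rows -> (classes, xyxy pixels)."""
    labels = np.asarray(labels, dtype=np.float64).reshape(-1, 5)
    cls = labels[:, 0].astype(np.int64)
    cx, cy, w, h = (labels[:, i] * imgsz for i in range(1, 5))
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
    return cls, boxes


def train_smoke(model, dataset, steps: int, seed: int = 0,
                cfg: TrainConfig | None = None) -> list[float]:
    """Run ``steps`` SGD steps over ``dataset`` and return the loss trace.

    ``dataset`` is a sequence of ``(image_hwc_uint8_or_float, labels)``
    pairs with YOLO-normalized labels.  Deterministic for a fixed seed.
    The total loss is lead + aux_weight x aux (aux term is identically zero
    when the model has no auxiliary head).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    imgsz = dataset[0][0].shape[0]
    images = [np.ascontiguousarray(
        np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0)
        for img, _ in dataset]
    targets = [_to_targets(lab, imgsz) for _, lab in dataset]

    model.train()
    loss_fn = DetectionLoss(num_classes=model.cfg.num_classes)
    opt = SGD(model.parameters(), cfg.lr0, cfg.momentum, cfg.weight_decay)
    trace = []
    n = len(images)
    for step in range(steps):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        batch = Tensor(np.stack([images[i] for i in idx]))
        out = model(batch)
        loss = loss_fn(out, [targets[i] for i in idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace
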