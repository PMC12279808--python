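"""Neural-network module system and the basic convolutional building blocks.

``Module`` mirrors the familiar container conventions: parameters are
``Tensor`` attributes with ``requires_grad=True``, submodules are discovered
by attribute walking, and ``train()`` / ``eval()`` toggle batch-norm
behaviour.  ``Conv`` is the conv + batch-norm + SiLU unit used throughout
both detector variants.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import (Tensor, concat, conv2d, max_pool2d, upsample_nearest2x)

__all__ = [
    "Module", "ModuleList", "Sequential", "Conv", "DWConv", "Conv2d",
    "BatchNorm2d", "MaxPool2d", "Upsample2x", "Concat", "SPPF", "autopad",
]


def autopad(k: int) -> int:
    return k // 2


class Module:
    def __init__(self) -> None:
        self.training = True

    # parameter / module discovery -------------------------------------
    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def modules(self):
        yield self
        for _, c in self._children():
            yield from c.modules()

    def parameters(self):
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield v

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _kaiming(shape, fan_in, rng) -> np.ndarray:
    bound = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


# default RNG used for weight init; reseeded by arch.build_model for
# reproducible construction
_INIT_RNG = np.random.default_rng(0)


def set_init_rng(seed: int) -> None:
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    """Raw convolution (optionally biased); no norm or activation."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, bias=True):
        super().__init__()
        self.stride, self.groups = s, g
        self.pad = autopad(k) if p is None else p
        fan_in = (c1 // g) * k * k
        self.weight = Tensor(_kaiming((c2, c1 // g, k, k), fan_in, _INIT_RNG),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c2, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad,
                      self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (
                var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class Conv(Module):
    """Conv2d + BatchNorm + activation (SiLU by default)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = act  # True → SiLU, False → identity, "relu" → ReLU

    def forward(self, x):
        x = self.bn(self.conv(x))
        if self.act is True:
            return x.silu()
        if self.act == "relu":
            return x.relu()
        return x


class DWConv(Conv):
    """Depthwise convolution block (groups = channels)."""

    def __init__(self, c1, c2, k=3, s=1, act=True):
        assert c1 == c2, "depthwise conv requires equal in/out channels"
        super().__init__(c1, c2, k, s, g=c1, act=act)


class MaxPool2d(Module):
    def __init__(self, k, s, p=0):
        super().__init__()
        self.k, self.s, self.p = k, s, p

    def forward(self, x):
        return max_pool2d(x, self.k, self.s, self.p)


class Upsample2x(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


class Concat(Module):
    def __init__(self, axis=1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return concat(xs, axis=self.axis)


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c_ * 4, c2, 1, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(concat(y, axis=1))
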