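"""Lightweight feature operators: GhostConv, SimAM and MLCA.

GhostConv produces only ``n/s`` of its output channels with a dense k×k
convolution; the remaining channels are cheap depthwise d×d transforms of
the primary ones, giving an ≈``s``-fold compression of parameters and FLOPs.

SimAM is a parameter-free attention: each activation ``t`` of a channel is
weighted by ``sigmoid(1/e*)`` where ``e* = 4(σ̂²+λ) / ((t−μ̂)² + 2σ̂² + 2λ)``
is the closed-form minimum of a binary-discrimination energy over the
channel's spatial positions (μ̂, σ̂² are the per-channel spatial mean and
variance).  Activations that stand out from their channel get low energy
and hence high weight.

MLCA (mixed local channel attention) pools the feature map to a small local
grid and to a global descriptor, runs a 1-D convolution across channels on
both, and fuses the two sigmoid gates back onto the input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, adaptive_avg_pool2d, concat, conv2d
from . import layers
from .layers import BatchNorm2d, Conv, Module

__all__ = [
    "FeatureMapSpec", "GhostConvSpec", "SimAMChannelStats", "MLCASpec",
    "ghost_ratios", "ghost_param_count", "ordinary_param_count",
    "simam_energy", "eca_kernel_size",
    "GhostConv", "SimAM", "MLCA",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureMapSpec:
    channels: int
    height: int
    width: int

    def __post_init__(self):
        if min(self.channels, self.height, self.width) < 1:
            raise ValueError("feature map dimensions must be >= 1")


@dataclass(frozen=True)
class GhostConvSpec:
    in_channels: int
    out_channels: int
    ratio: int = 2          # s: fraction of channels computed densely = 1/s
    primary_kernel: int = 3  # k
    cheap_kernel: int = 3    # d (depthwise)
    stride: int = 1

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("ratio s must be >= 1")
        if self.out_channels % self.ratio:
            raise ValueError(
                f"out_channels={self.out_channels} not divisible by s={self.ratio}")
        if self.primary_kernel % 2 == 0 or self.cheap_kernel % 2 == 0:
            raise ValueError("kernels must be odd")


@dataclass(frozen=True)
class SimAMChannelStats:
    mean: float
    variance: float
    lam: float = 1e-4

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass(frozen=True)
class MLCASpec:
    channels: int
    local_grid: int = 5
    conv1d_kernel: int = field(default=0)  # 0 → derive ECA-style from channels

    def __post_init__(self):
        if self.local_grid < 1:
            raise ValueError("local grid must be >= 1")
        k = self.conv1d_kernel or eca_kernel_size(self.channels)
        if k % 2 == 0:
            raise ValueError("conv1d kernel must be odd")
        object.__setattr__(self, "conv1d_kernel", k)


# ---------------------------------------------------------------------------
# Ghost convolution
# ---------------------------------------------------------------------------

def ordinary_param_count(c: int, n: int, k: int) -> int:
    """Kernel weights of a dense c→n k×k convolution (bias/BN excluded)."""
    return n * c * k * k


def ghost_param_count(spec: GhostConvSpec) -> int:
    """Kernel weights of the ghost factorization (bias/BN excluded)."""
    c, n, s = spec.in_channels, spec.out_channels, spec.ratio
    k, d = spec.primary_kernel, spec.cheap_kernel
    primary = (n // s) * c * k * k
    cheap = (n - n // s) * d * d  # depthwise: d*d weights per cheap channel
    return primary + cheap


def ghost_ratios(spec: GhostConvSpec,
                 out_spatial: FeatureMapSpec | None = None) -> tuple[float, float]:
    """(speedup R_S, compression R_C) of ghost vs ordinary convolution.

    Both ratios reduce to s·c·k² / (c·k² + (s−1)·d²); the spatial extent
    cancels from the FLOP ratio, so ``out_spatial`` only validates shape.
    """
    c, s = spec.in_channels, spec.ratio
    k, d = spec.primary_kernel, spec.cheap_kernel
    denom = c * k * k + (s - 1) * d * d
    r = s * c * k * k / denom
    return r, r


class GhostConv(Module):
    """Dense primary convolution + depthwise cheap branch, concatenated.

    Primary branch: c → n/s, k×k, BN + SiLU.  Cheap branch: each primary
    channel is expanded into s−1 extra channels via depthwise d×d
    convolution with BN (no activation).  s=1 degenerates to an ordinary
    dense convolution.
    """

    def __init__(self, c1, c2, k=3, s_stride=1, ratio=2, d=3):
        super().__init__()
        self.spec = GhostConvSpec(c1, c2, ratio, k, d, s_stride)
        cp = c2 // ratio
        self.primary = Conv(c1, cp, k, s_stride)
        if ratio > 1:
            self.cheap_w = Tensor(
                layers._INIT_RNG.normal(
                    0, math.sqrt(2.0 / (d * d)),
                    size=(cp * (ratio - 1), 1, d, d)).astype(np.float32),
                requires_grad=True)
            self.cheap_bn = BatchNorm2d(c2 - cp)
            self._d = d

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}")
        y = self.primary(x)
        if self.spec.ratio == 1:
            return y
        cp = y.shape[1]
        rep = self.spec.ratio - 1
        # each primary channel feeds rep cheap filters (depthwise on tiled y)
        ys = concat([y] * rep, axis=1) if rep > 1 else y
        cheap = conv2d(ys, self.cheap_w, None, 1, self._d // 2, groups=cp * rep)
        return concat([y, self.cheap_bn(cheap)], axis=1)


# ---------------------------------------------------------------------------
# SimAM
# ---------------------------------------------------------------------------

def simam_energy(t: float, stats: SimAMChannelStats) -> float:
    """Closed-form minimal energy e* of the target activation ``t``.

    e* = 4(σ̂²+λ) / ((t−μ̂)² + 2σ̂² + 2λ); strictly positive, equal to 2
    when t = μ̂, and strictly decreasing in |t−μ̂|.
    """
    dev2 = (t - stats.mean) ** 2
    return 4.0 * (stats.variance + stats.lam) / (dev2 + 2 * stats.variance
                                                 + 2 * stats.lam)


class SimAM(Module):
    """Parameter-free 3-D attention; adds zero learnable parameters."""

    def __init__(self, lam: float = 1e-4):
        super().__init__()
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        self.lam = lam

    def forward(self, x):
        n, c, h, w = x.shape
        m = h * w
        if m < 2:
            warnings.warn("SimAM on a single-pixel channel: input returned "
                          "unchanged (degenerate statistics)")
            return x
        mu = x.mean(axis=(2, 3), keepdims=True)
        d = x - mu
        d2 = d * d
        # spatial variance with the (M-1) denominator
        var = d2.sum(axis=(2, 3), keepdims=True) * (1.0 / (m - 1))
        inv_e = (d2 + 2 * var + 2 * self.lam) / (4.0 * (var + self.lam))
        return x * inv_e.sigmoid()


# ---------------------------------------------------------------------------
# MLCA
# ---------------------------------------------------------------------------

def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """ECA rule: nearest odd integer to |log2(C)/gamma + b/gamma|."""
    k = int(abs(math.log2(channels) / gamma + b / gamma))
    return k if k % 2 else k + 1


class _Conv1dAcrossChannels(Module):
    """1-D convolution (1 in / 1 out channel, no bias) along the last axis."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k
        self.weight = Tensor(
            layers._INIT_RNG.normal(0, math.sqrt(1.0 / k),
                                    size=(1, 1, 1, k)).astype(np.float32),
            requires_grad=True)

    def forward(self, x):  # x: (B, 1, L) as Tensor shaped (B, 1, 1, L)
        return conv2d(x, self.weight, None, 1, (0, self.k // 2))


class MLCA(Module):
    """Mixed local channel attention gate.

    Local branch: average-pool to g×g, 1-D conv across channels per grid
    cell.  Global branch: global average pool, 1-D conv across channels.
    The two sigmoid gates are blended 50/50, upsampled and multiplied onto
    the input.  Learnable parameters: the two 1-D kernels only (2k weights).
    """

    def __init__(self, channels: int, local_grid: int = 5,
                 conv1d_kernel: int | None = None):
        super().__init__()
        self.spec = MLCASpec(channels, local_grid, conv1d_kernel or 0)
        k = self.spec.conv1d_kernel
        self.conv_local = _Conv1dAcrossChannels(k)
        self.conv_global = _Conv1dAcrossChannels(k)
        self.local_weight = 0.5

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.spec.channels:
            raise ValueError(f"expected {self.spec.channels} channels, got {c}")
        g = self.spec.local_grid
        local = adaptive_avg_pool2d(x, (g, g))            # (N,C,g,g)
        glob = local.mean(axis=(2, 3), keepdims=True)     # (N,C,1,1)
        # channel axis last for the 1-D convs
        tl = local.reshape(n, c, g * g).transpose(0, 2, 1).reshape(n, 1, 1, g * g * c)
        tg = glob.reshape(n, c, 1).transpose(0, 2, 1).reshape(n, 1, 1, c)
        yl = self.conv_local(tl).reshape(n, g * g, c).transpose(0, 2, 1) \
            .reshape(n, c, g, g).sigmoid()
        yg = self.conv_global(tg).reshape(n, 1, c).transpose(0, 2, 1) \
            .reshape(n, c, 1, 1).sigmoid()
        gate = yl * self.local_weight + yg * (1.0 - self.local_weight)
        # broadcast the g×g gate back to full resolution (nearest-bin)
        yi = np.minimum((np.arange(h) * g) // h, g - 1)
        xi = np.minimum((np.arange(w) * g) // w, g - 1)
        gate_full = gate[:, :, yi][:, :, :, xi]
        return x * gate_full
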