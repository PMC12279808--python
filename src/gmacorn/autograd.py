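"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set the detector stack needs: broadcasted
arithmetic, matmul, elementwise nonlinearities, reductions, shape ops,
2-D convolution (grouped / depthwise), max pooling, nearest upsampling and
adaptive average pooling.  Gradients flow through a tape built at forward
time; ``Tensor.backward()`` runs the tape in reverse topological order.

All computation is float32 unless the caller supplies float64 data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "concat", "profiler", "Profiler"]

_GRAD_ENABLED = True


def stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class no_grad:
    """Context manager disabling tape construction (inference / assignment)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Profiler:
    """Collects multiply-accumulate counts emitted by conv/linear forwards."""

    _active: list["Profiler"] = []

    def __init__(self) -> None:
        self.macs = 0

    def __enter__(self):
        Profiler._active.append(self)
        return self

    def __exit__(self, *exc):
        Profiler._active.remove(self)
        return False

    @staticmethod
    def record(macs: int) -> None:
        for p in Profiler._active:
            p.macs += macs


def profiler() -> Profiler:
    return Profiler()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad or any(
            isinstance(p, Tensor) and p.requires_grad for p in parents
        ) else ()
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction ----------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        t = Tensor(data, requires_grad=needs)
        if needs:
            t._parents = parents
            t._backward = backward
        return t

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        Profiler.record(int(np.prod(self.data.shape)) * other.data.shape[-1])

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- nonlinearities ---------------------------------------------------
    def sigmoid(self):
        s = stable_sigmoid(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1 - s))

        return Tensor._make(s, (self,), bw)

    def silu(self):
        s = stable_sigmoid(self.data)
        out = self.data * s

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s + out * (1 - s)))

        return Tensor._make(out, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out)

        return Tensor._make(out, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out, 1e-12))

        return Tensor._make(out, (self,), bw)

    def arctan(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data ** 2))

        return Tensor._make(np.arctan(self.data), (self,), bw)

    def clamp(self, lo=None, hi=None):
        out = np.clip(self.data, lo, hi)
        interior = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            interior &= self.data > lo
        if hi is not None:
            interior &= self.data < hi

        def bw(g):
            if self.requires_grad:
                self._accum(g * interior)

        return Tensor._make(out, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return Tensor._make(s, (self,), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accum(buf)

        return Tensor._make(self.data[idx], (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out = np.concatenate([t.data for t in tensors], axis=axis)
    parents = tuple(tensors)
    return Tensor._make(out, parents, bw)


# ---------------------------------------------------------------------------
# Convolution & pooling primitives
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """View of shape (N, C, OH, OW, KH, KW) over the padded input."""
    n, c, h, w = xp.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    sn, sc, sh_, sw_ = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, oh, ow, kh, kw),
        strides=(sn, sc, sh_ * sh, sw_ * sw, sh_, sw_),
        writeable=False,
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: tuple[int, int] | int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation; records MACs with any active profiler."""
    if isinstance(padding, int):
        padding = (padding, padding)
    ph, pw = padding
    co, cig, kh, kw = w.shape
    n, ci, _, _ = x.shape
    assert ci == cig * groups, "channel/group mismatch"
    xp = _pad_hw(x.data, ph, pw)
    win = _windows(xp, kh, kw, stride, stride)
    oh, ow = win.shape[2], win.shape[3]
    Profiler.record(n * oh * ow * co * cig * kh * kw)

    if groups == ci and co == ci and cig == 1:
        # depthwise
        out = np.einsum("nchwkl,ckl->nchw", win, w.data[:, 0], optimize=True)
    elif groups == 1:
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, ci * kh * kw)
        out = (cols @ w.data.reshape(co, -1).T).reshape(n, oh, ow, co)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    else:
        outs = []
        wg = w.data.reshape(groups, co // groups, cig, kh, kw)
        for g in range(groups):
            sub = win[:, g * cig:(g + 1) * cig]
            cols = sub.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, cig * kh * kw)
            og = (cols @ wg[g].reshape(co // groups, -1).T)
            outs.append(og.reshape(n, oh, ow, co // groups))
        out = np.ascontiguousarray(np.concatenate(outs, axis=3).transpose(0, 3, 1, 2))
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gy = g  # (N, Co, OH, OW)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))
        cog = co // groups
        gyg = gy.reshape(n, groups, cog, oh, ow)
        if w.requires_grad:
            wing = win.reshape(n, groups, cig, oh, ow, kh, kw)
            gw = np.einsum("ngihwkl,ngohw->goikl", wing, gyg, optimize=True)
            w._accum(gw.reshape(co, cig, kh, kw))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            wgr = w.data.reshape(groups, cog, cig, kh, kw)
            for kk in range(kh):
                for ll in range(kw):
                    # (N,G,Cig,OH,OW) contribution
                    contrib = np.einsum(
                        "goi,ngohw->ngihw", wgr[:, :, :, kk, ll], gyg, optimize=True
                    ).reshape(n, ci, oh, ow)
                    gxp[:, :, kk:kk + oh * stride:stride,
                        ll:ll + ow * stride:stride] += contrib
            if ph or pw:
                gxp = gxp[:, :, ph:ph + x.shape[2], pw:pw + x.shape[3]]
            x._accum(gxp)

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, k: int, stride: int, padding: int = 0) -> Tensor:
    xp = _pad_hw(x.data, padding, padding)
    if padding:
        xp[:, :, :padding] = -np.inf
        xp[:, :, -padding:] = -np.inf
        xp[:, :, :, :padding] = -np.inf
        xp[:, :, :, -padding:] = -np.inf
    win = _windows(xp, k, k, stride, stride)
    n, c, oh, ow = win.shape[:4]
    flat = win.reshape(n, c, oh, ow, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, xp.shape[2], xp.shape[3]), dtype=x.data.dtype)
        ky, kx = np.divmod(arg, k)
        oy = np.arange(oh)[None, None, :, None] * stride
        ox = np.arange(ow)[None, None, None, :] * stride
        ni = np.arange(n)[:, None, None, None]
        ci_ = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (ni, ci_, oy + ky, ox + kx), g)
        if padding:
            gxp = gxp[:, :, padding:padding + x.shape[2], padding:padding + x.shape[3]]
        x._accum(gxp)

    return Tensor._make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average pool to an arbitrary output grid (integer bin edges)."""
    n, c, h, w = x.shape
    gh, gw = out_hw
    if h < gh or w < gw:
        raise ValueError(f"spatial size ({h},{w}) smaller than pool grid ({gh},{gw})")
    ye = [int(np.floor(i * h / gh)) for i in range(gh + 1)]
    xe = [int(np.floor(j * w / gw)) for j in range(gw + 1)]
    out = np.empty((n, c, gh, gw), dtype=x.data.dtype)
    for i in range(gh):
        for j in range(gw):
            out[:, :, i, j] = x.data[:, :, ye[i]:ye[i + 1], xe[j]:xe[j + 1]].mean(
                axis=(2, 3))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i in range(gh):
            for j in range(gw):
                area = (ye[i + 1] - ye[i]) * (xe[j + 1] - xe[j])
                gx[:, :, ye[i]:ye[i + 1], xe[j]:xe[j + 1]] += (
                    g[:, :, i:i + 1, j:j + 1] / area)
        x._accum(gx)

    return Tensor._make(out, (x,), bw)
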