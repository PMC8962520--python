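"""Minimal reverse-mode automatic differentiation over numpy arrays.

Array-valued tape autodiff with exactly the operations the enhancement
network needs: elementwise arithmetic, activations, 2-D convolution via
im2col, nearest-neighbour upsampling, channel concatenation, reductions and
a numerically guarded binary cross-entropy.  float32 throughout.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _needs(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if _needs(a):
            a._accumulate(g)
        if _needs(b):
            b._accumulate(g)
    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if _needs(a):
            a._accumulate(g)
        if _needs(b):
            b._accumulate(-g)
    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if _needs(a):
            a._accumulate(g * b.data)
        if _needs(b):
            b._accumulate(g * a.data)
    return _make(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if _needs(a):
            a._accumulate(g / b.data)
        if _needs(b):
            b._accumulate(-g * a.data / (b.data * b.data))
    return _make(a.data / b.data, (a, b), backward)


def add_const(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a._accumulate(g)
    return _make(a.data + _F32(c), (a,), backward)


def mul_const(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a._accumulate(g * _F32(c))
    return _make(a.data * _F32(c), (a,), backward)


def scale(x: Tensor, s: Tensor) -> Tensor:
    """Multiply an array tensor by a scalar (shape-()) tensor."""
    def backward(g):
        if _needs(x):
            x._accumulate(g * s.data)
        if _needs(s):
            s._accumulate(np.asarray((g * x.data).sum(), dtype=_F32))
    return _make(x.data * s.data, (x, s), backward)


# --------------------------------------------------------------- activations

def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(np.where(mask, g, g * _F32(slope)))
    return _make(np.where(mask, x.data, x.data * _F32(slope)), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * y * (1.0 - y))
    return _make(y, (x,), backward)


# ---------------------------------------------------------------- reductions

def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        x._accumulate(np.full_like(x.data, g / n))
    return _make(np.asarray(x.data.mean(), dtype=_F32), (x,), backward)


# -------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh * kw, ho, wo), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = \
                x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=_F32)
    cols = cols.reshape(n, c, kh * kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += \
                cols[:, :, i * kw + j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) of (N,C,H,W) with (Co,C,kh,kw)."""
    co, ci, kh, kw = weight.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    w2 = weight.data.reshape(co, ci * kh * kw)
    y = np.matmul(w2, cols)  # (N, Co, Ho*Wo)
    if bias is not None:
        y += bias.data[None, :, None]
    y = y.reshape(n, co, ho, wo)

    def backward(g):
        gy = g.reshape(n, co, ho * wo)
        if _needs(weight):
            gw = np.einsum("ncl,nkl->ck", gy, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and _needs(bias):
            bias._accumulate(gy.sum(axis=(0, 2)))
        if _needs(x):
            gcols = np.matmul(w2.T, gy)  # (N, C*kh*kw, L)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


def sep_filter_valid(x: Tensor, kernel_1d: np.ndarray) -> Tensor:
    """Separable symmetric filtering of (N,C,H,W), valid region only.

    Used for the Gaussian windows of the SSIM loss; the kernel is fixed
    (never trained) and symmetric, so the input gradient is the zero-padded
    gradient filtered with the same kernel.
    """
    from scipy.ndimage import convolve1d

    k = np.asarray(kernel_1d, dtype=_F32)
    if k.ndim != 1 or len(k) % 2 == 0:
        raise ValueError("kernel must be 1-D with odd length")
    m = len(k) // 2

    def filt(a: np.ndarray) -> np.ndarray:
        out = convolve1d(a, k, axis=-2, mode="constant")
        out = convolve1d(out, k, axis=-1, mode="constant")
        return out[..., m:-m, m:-m]

    y = filt(x.data)

    def backward(g):
        gp = np.zeros_like(x.data)
        gp[..., m:-m, m:-m] = g
        x._accumulate(filt(np.pad(gp, ((0, 0), (0, 0), (m, m), (m, m)))))
    return _make(y, (x,), backward)


# ----------------------------------------------------------- shape plumbing

def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of (N,C,H,W)."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        gs = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(gs)
    return _make(y, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _needs(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


# -------------------------------------------------------------------- losses

def bce(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Mean pixel-wise binary cross-entropy of [0,1] intensities."""
    t = np.asarray(target, dtype=_F32)
    p = np.clip(pred.data, eps, 1.0 - eps)
    val = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()

    def backward(g):
        pred._accumulate(g * (p - t) / (p * (1.0 - p)) / p.size)
    return _make(np.asarray(val, dtype=_F32), (pred,), backward)
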