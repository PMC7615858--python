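"""Minimal tape-based reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the hierarchical VAE needs: elementwise
arithmetic with broadcasting, common nonlinearities, reductions, concatenation,
2-D (grouped by special cases: dense and depthwise) convolution, nearest
upsampling, and a numerically stable binary cross-entropy with logits.

Gradients are accumulated by a topological backward sweep over the recorded
graph. Arrays are not modified in place; every op returns a fresh ``Tensor``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "upsample_nearest",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected dunders instead of building object arrays
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _parents=parents, _backward=backward)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros(self.data.shape, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node; seeds with ones if no grad given."""
        if grad is None:
            grad = np.ones(self.data.shape, dtype=self.data.dtype)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node.grad = None  # interior gradient no longer needed

    # -- arithmetic --------------------------------------------------------
    # python scalars are applied directly (never wrapped into 0-d arrays,
    # which would promote float32 graphs to float64)
    def __add__(self, other):
        if isinstance(other, (int, float)):
            c = other

            def back_s(g):
                self._accumulate(g)

            return Tensor._make(self.data + c, (self,), back_s)
        other = as_tensor(other)
        out_data = self.data + other.data

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = other

            def back_s(g):
                self._accumulate(g * c)

            return Tensor._make(self.data * c, (self,), back_s)
        other = as_tensor(other)
        out_data = self.data * other.data

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), back)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            c = other
            out_data = c / self.data

            def back_s(g):
                self._accumulate(-g * out_data / self.data)

            return Tensor._make(out_data, (self,), back_s)
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def back(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), back)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), back)

    def log(self):
        def back(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            self._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), back)

    def sigmoid(self):
        # stable: use tanh identity
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def back(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), back)

    def swish(self):
        """x * sigmoid(x) (a.k.a. SiLU)."""
        s = 0.5 * (np.tanh(0.5 * self.data) + 1.0)
        out_data = self.data * s

        def back(g):
            self._accumulate(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(out_data, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope).astype(self.data.dtype)

        def back(g):
            self._accumulate(g * scale)

        return Tensor._make(self.data * scale, (self,), back)

    def abs(self):
        sign = np.sign(self.data)

        def back(g):
            self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), back)

    def clamp(self, lo: float, hi: float):
        """Hard clamp; gradient is passed only where the input is in range."""
        mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)

        def back(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), back)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def slice_channels(self, lo: int, hi: int):
        """View of channels [lo, hi) along axis 1 (NCHW)."""
        out_data = self.data[:, lo:hi]

        def back(g):
            full = np.zeros(self.data.shape, dtype=self.data.dtype)
            full[:, lo:hi] = g
            self._accumulate(full)

        return Tensor._make(np.ascontiguousarray(out_data), (self,), back)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def back(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor._make(out_data, (self,), back)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), back)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=x.dtype)
    out[:, :, p:h + p, p:w + p] = x
    return out


def _out_size(size: int, k: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - k) // stride + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW, OIHW weights.

    Implemented tap-wise: one batched channel-mixing matmul per kernel
    offset, accumulated over the (kh * kw) taps. This keeps every copy
    row-contiguous and every GEMM large, which is what NumPy does fast.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h_in, w_in = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input channels {cin} != weight channels {cin_w}")

    if kh == 1 and kw == 1 and stride == 1 and padding == 0:
        # fast path: pure channel mixing
        xm = x.data.reshape(n, cin, h_in * w_in)
        out_data = np.matmul(w.data[:, :, 0, 0], xm).reshape(n, cout, h_in, w_in)
        if b is not None:
            out_data += b.data[None, :, None, None]

        def back1(g):
            gm = g.reshape(n, cout, h_in * w_in)
            if w.requires_grad:
                gw = np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
                w._accumulate(gw[:, :, None, None])
            if x.requires_grad:
                gx = np.matmul(w.data[:, :, 0, 0].T, gm)
                x._accumulate(gx.reshape(n, cin, h_in, w_in))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out_data, parents, back1)

    xp = _pad_hw(x.data, padding)
    oh = _out_size(h_in, kh, stride, padding)
    ow = _out_size(w_in, kw, stride, padding)
    def tap(i, j):
        return np.ascontiguousarray(
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
        ).reshape(n, cin, oh * ow)

    out_flat = np.zeros((n, cout, oh * ow), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_flat += np.matmul(w.data[:, :, i, j], tap(i, j))
    out_data = out_flat.reshape(n, cout, oh, ow)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def back(g):
        gm = g.reshape(n, cout, oh * ow)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, :, i, j] = np.matmul(gm, tap(i, j).transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            wt = w.data.transpose(2, 3, 1, 0)  # (kh, kw, C, O)
            for i in range(kh):
                for j in range(kw):
                    gsl = np.matmul(wt[i, j], gm).reshape(n, cin, oh, ow)
                    gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += gsl
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, back)


def depthwise_conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Per-channel 2-D convolution; weights shaped (C, kh, kw). Tap-wise."""
    x, w = as_tensor(x), as_tensor(w)
    c, kh, kw = w.data.shape
    n, cx, h_in, w_in = x.data.shape
    if cx != c:
        raise ValueError("depthwise_conv2d: channel mismatch")
    xp = _pad_hw(x.data, padding)
    oh = _out_size(h_in, kh, stride, padding)
    ow = _out_size(w_in, kw, stride, padding)
    out_data = np.zeros((n, c, oh, ow), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] \
                * w.data[None, :, i, j, None, None]

    def back(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    sl = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
                    gw[:, i, j] = (g * sl).sum(axis=(0, 2, 3))
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                        g * w.data[None, :, i, j, None, None]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out_data, (x, w), back)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def back(g):
        n, c, h, w = x.data.shape
        g = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(g)

    return Tensor._make(out_data, (x,), back)


def bce_with_logits(logits: Tensor, target: float | np.ndarray) -> Tensor:
    """Mean binary cross-entropy with logits; target is a constant.

    Stable form: max(x, 0) - x*t + log(1 + exp(-|x|)), reduced by mean.
    """
    logits = as_tensor(logits)
    x = logits.data
    t = np.broadcast_to(np.asarray(target, dtype=x.dtype), x.shape)
    val = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out_data = val.mean(dtype=np.float64).astype(x.dtype)

    def back(g):
        s = 0.5 * (np.tanh(0.5 * x) + 1.0)
        logits._accumulate((g * (s - t) / x.size).astype(x.dtype))

    return Tensor._make(out_data, (logits,), back)
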