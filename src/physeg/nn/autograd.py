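"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the segmentation network and its losses
need: broadcasting arithmetic, matmul, 3-D convolution (shift-and-matmul
for 3x3x3 kernels), separable trilinear resampling expressed as per-axis
matrix products, pointwise nonlinearities, reductions, concatenation and
slicing.  Values are float64 throughout; execution is single-threaded
numpy, so results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "axis_matmul", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        d = np.asarray(data)
        if not np.issubdtype(d.dtype, np.floating):
            d = d.astype(np.float64)
        self.data = d
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            # copy: grad may be a view into another node's buffer
            self.grad = np.array(grad, dtype=self.data.dtype)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )
        return Tensor._make(self.data / other.data, (self, other), bw)

    def __pow__(self, k: float):
        def bw(g):
            self._accum(g * k * self.data ** (k - 1))
        return Tensor._make(self.data**k, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def bw(g):
            self._accum(g * out_data)
        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bw)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        def bw(g):
            self._accum(g * np.where(mask, 1.0, slope))
        return Tensor._make(np.where(mask, self.data, slope * self.data), (self,), bw)

    def softplus(self):
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        def bw(g):
            self._accum(g * sig)
        return Tensor._make(out_data, (self,), bw)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape
        def bw(g):
            self._accum(g.reshape(orig))
        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            buf = np.zeros_like(self.data)
            buf[idx] = g
            self._accum(buf)
        return Tensor._make(self.data[idx], (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3-D convolution, kernel 3x3x3, zero padding 1.

    ``x``: (N, Cin, D, H, W); ``w``: (Cout, Cin, 3, 3, 3); ``b``: (Cout,).
    Implemented as a sum of 27 shifted channel-mixing matmuls, which keeps
    both passes as dense BLAS calls.
    """
    N, Cin, D, H, W = x.data.shape
    Cout = w.data.shape[0]
    s = stride
    Do, Ho, Wo = (D - 1) // s + 1, (H - 1) // s + 1, (W - 1) // s + 1
    V = N * Do * Ho * Wo
    dtype = np.result_type(x.data.dtype, w.data.dtype)
    # channel-first internal layout (Cin, N, D, H, W) keeps the 27
    # shifted slices reshape-cheap for the channel-mixing matmuls
    xp = np.pad(
        np.ascontiguousarray(x.data.transpose(1, 0, 2, 3, 4), dtype=dtype),
        ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)),
    )

    offsets = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]
    slices = [
        (
            slice(None),
            slice(None),
            slice(i, i + s * (Do - 1) + 1, s),
            slice(j, j + s * (Ho - 1) + 1, s),
            slice(k, k + s * (Wo - 1) + 1, s),
        )
        for i, j, k in offsets
    ]
    wd = w.data.astype(dtype, copy=False)
    out = np.zeros((Cout, V), dtype=dtype)
    for (i, j, k), sl in zip(offsets, slices):
        out += wd[:, :, i, j, k] @ xp[sl].reshape(Cin, V)
    out = out.reshape(Cout, N, Do, Ho, Wo).transpose(1, 0, 2, 3, 4)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) + ((b,) if b is not None else ())

    def bw(g):
        g2 = np.ascontiguousarray(
            g.transpose(1, 0, 2, 3, 4), dtype=dtype
        ).reshape(Cout, V)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        gw = np.zeros_like(wd) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for (i, j, k), sl in zip(offsets, slices):
            if w.requires_grad:
                gw[:, :, i, j, k] = g2 @ xp[sl].reshape(Cin, V).T
            if x.requires_grad:
                gxp[sl] += (wd[:, :, i, j, k].T @ g2).reshape(
                    Cin, N, Do, Ho, Wo
                )
        if w.requires_grad:
            w._accum(gw)
        if x.requires_grad:
            x._accum(
                gxp[:, :, 1:-1, 1:-1, 1:-1].transpose(1, 0, 2, 3, 4)
            )

    return Tensor._make(out, parents, bw)


def axis_matmul(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """Apply the fixed matrix ``m`` (out_len, in_len) along one axis of x.

    Used for separable trilinear up-sampling; ``m`` is constant, so only
    ``x`` receives gradient (via m.T).
    """
    m = m.astype(x.data.dtype, copy=False)
    data = np.moveaxis(
        np.tensordot(x.data, m, axes=([axis], [1])), -1, axis
    )
    def bw(g):
        gx = np.moveaxis(np.tensordot(g, m, axes=([axis], [0])), -1, axis)
        x._accum(gx)
    return Tensor._make(data, (x,), bw)


def logsumexp(x: Tensor, axis: int) -> Tensor:
    """Numerically stable log-sum-exp; the shift is treated as constant."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    out = (x - shift).exp().sum(axis=axis, keepdims=True).log() + shift
    return out
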