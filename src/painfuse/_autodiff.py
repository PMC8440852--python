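"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operation set needed by the 1-D convolutional
encoder/decoder stack: broadcast arithmetic, matmul, the usual pointwise
activations, reductions, reshape/concat, same-padded 1-D convolution
(im2col formulation), max-pooling and nearest-neighbour upsampling along
the time axis, and channel-axis max (for the attention module's pooling).

Gradient correctness is enforced by central-difference checks in the test
suite; keep new operations covered there.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "upsample1d", "chanmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._prev = prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self):
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def back():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = back
        return out

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data**p, (self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda: self._accum(out.grad * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda: self._accum(out.grad * out.data * (1.0 - out.data))
        return out

    def elu(self):
        """Exponential linear unit with alpha = 1."""
        x = self.data
        out = Tensor(np.where(x >= 0, x, np.expm1(x)), (self,))
        out._backward = lambda: self._accum(
            out.grad * np.where(x >= 0, 1.0, out.data + 1.0)
        )
        return out

    def softplus(self):
        # log(1 + exp(x)), computed stably
        out = Tensor(np.logaddexp(0.0, self.data), (self,))
        out._backward = lambda: self._accum(
            out.grad / (1.0 + np.exp(-self.data))
        )
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def back():
            g = np.zeros_like(self.data)
            g[idx] += out.grad
            self._accum(g)

        out._backward = back
        return out

    def clip_min(self, lo):
        """max(x, lo) with sub-gradient 1 where x > lo (used for eps-clipping)."""
        mask = self.data > lo
        out = Tensor(np.where(mask, self.data, lo), (self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out._backward = back
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 1-D convolution.

    x: (N, W, Cin); w: (K, Cin, Cout), K odd; b: (Cout,) or None.
    Computed as a sum of K time-shifted matmuls (one per kernel tap), which
    keeps forward and both gradients inside BLAS without materializing
    im2col patch matrices.
    """
    K, Cin, Cout = w.shape
    assert K % 2 == 1, "same padding requires an odd kernel"
    pad = K // 2
    N, W, _ = x.shape

    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    out_data = np.zeros((N, W, Cout))
    for k in range(K):
        out_data += xp[:, k:k + W, :] @ w.data[k]
    if b is not None:
        out_data += b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, prev)

    def back():
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for k in range(K):
                # batched (Cin, W) @ (W, Cout), summed over the batch
                dw[k] = np.matmul(xp[:, k:k + W, :].transpose(0, 2, 1), g).sum(axis=0)
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k:k + W, :] += g @ w.data[k].T
            x._accum(dxp[:, pad:pad + W, :])

    out._backward = back
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along the time axis; W must divide by size."""
    N, W, C = x.shape
    assert W % size == 0
    xr = x.data.reshape(N, W // size, size, C)
    idx = xr.argmax(axis=2)
    out = Tensor(xr.max(axis=2), (x,))

    def back():
        gz = np.zeros((N, W // size, size, C))
        np.put_along_axis(gz, idx[:, :, None, :], out.grad[:, :, None, :], axis=2)
        x._accum(gz.reshape(N, W, C))

    out._backward = back
    return out


def upsample1d(x: Tensor, size: int = 2) -> Tensor:
    """Nearest-neighbour repetition along the time axis."""
    N, W, C = x.shape
    out = Tensor(np.repeat(x.data, size, axis=1), (x,))
    out._backward = lambda: x._accum(
        out.grad.reshape(N, W, size, C).sum(axis=2)
    )
    return out


def chanmax(x: Tensor) -> Tensor:
    """Max over the channel (last) axis, keepdims; gradient to the argmax."""
    idx = x.data.argmax(axis=-1)
    out = Tensor(x.data.max(axis=-1, keepdims=True), (x,))

    def back():
        gz = np.zeros_like(x.data)
        np.put_along_axis(gz, idx[..., None], out.grad, axis=-1)
        x._accum(gz)

    out._backward = back
    return out
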