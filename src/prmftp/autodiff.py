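"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the peptide network needs: broadcast
arithmetic, (batched) matrix products, the sigmoid/tanh/ReLU/exp/log family,
axis reductions, slicing/concatenation/reshaping, row softmax, an embedding
lookup, a "same"-padded 1-D convolution and non-overlapping max pooling.
Gradients are accumulated on a tape and released by :meth:`Tensor.backward`.

All arrays are float64; determinism is inherited from numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were prepended
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor.__r*__ in mixed ndarray-Tensor expressions
    __array_priority__ = 1000.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g, a=self, y=y):
            a._accum(g * (1.0 - y**2))

        return Tensor._make(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g, a=self, y=y):
            a._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, mask=mask):
            a._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g, a=self, y=y):
            a._accum(g * y)

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through unclipped entries."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self, mask=mask):
            a._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(ge, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; ties route the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g, a=self, idx=idx):
            ge = g if keepdims else np.expand_dims(g, axis)
            buf = np.zeros_like(a.data)
            np.put_along_axis(buf, np.expand_dims(idx, axis), ge, axis=axis)
            a._accum(buf)

        data = out if keepdims else np.squeeze(out, axis=axis)
        return Tensor._make(data, (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        def backward(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        def backward(g, a=self):
            a._accum(np.swapaxes(g, a1, a2))

        return Tensor._make(np.swapaxes(self.data, a1, a2), (self,), backward)

    def __getitem__(self, key):
        def backward(g, a=self, key=key):
            buf = np.zeros_like(a.data)
            buf[key] = g  # basic slices only: no index repeats, assignment is exact
            a._accum(buf)

        return Tensor._make(self.data[key], (self,), backward)

    # -- softmax --------------------------------------------------------------

    def softmax(self):
        """Numerically stable softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g, a=self, s=s):
            dot = (g * s).sum(axis=-1, keepdims=True)
            a._accum(s * (g - dot))

        return Tensor._make(s, (self,), backward)

    # -- structured ops -------------------------------------------------------

    @staticmethod
    def embedding(weight: "Tensor", tokens: np.ndarray) -> "Tensor":
        """Row lookup ``weight[tokens]`` with scatter-add gradient."""
        tokens = np.asarray(tokens)

        def backward(g, w=weight, tokens=tokens):
            if w.requires_grad:
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                np.add.at(w.grad, tokens.reshape(-1), g.reshape(-1, w.data.shape[1]))

        return Tensor._make(weight.data[tokens], (weight,), backward)

    def conv1d_same(self, weight: "Tensor", bias: "Tensor", kernel: int) -> "Tensor":
        """1-D convolution with 'same' zero padding.

        Input (N, L, C), weight (kernel*C, F), bias (F,) -> output (N, L, F).
        """
        x = self.data
        n, length, c = x.shape
        left = (kernel - 1) // 2
        right = kernel - 1 - left
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        # cols[n, t, j, c] = xp[n, t + j, c]
        cols = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
        cols = np.ascontiguousarray(np.swapaxes(cols, 2, 3)).reshape(n, length, kernel * c)
        out = cols @ weight.data + bias.data

        def backward(g, a=self, w=weight, b=bias, cols=cols):
            if w.requires_grad:
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad += cols.reshape(-1, kernel * c).T @ g.reshape(-1, g.shape[-1])
            if b.requires_grad:
                if b.grad is None:
                    b.grad = np.zeros_like(b.data)
                b.grad += g.sum(axis=(0, 1))
            if a.requires_grad:
                dcols = (g @ w.data.T).reshape(n, length, kernel, c)
                dxp = np.zeros((n, length + kernel - 1, c))
                for j in range(kernel):
                    dxp[:, j : j + length, :] += dcols[:, :, j, :]
                a._accum(dxp[:, left : left + length, :])

        return Tensor._make(out, (self, weight, bias), backward)

    def maxpool1d(self, size: int) -> "Tensor":
        """Non-overlapping max pool along axis 1 of (N, L, C); trailing
        positions that do not fill a window are dropped."""
        n, length, c = self.data.shape
        lp = length // size
        x = self.data[:, : lp * size, :].reshape(n, lp, size, c)
        idx = np.argmax(x, axis=2)
        out = np.take_along_axis(x, idx[:, :, None, :], axis=2)[:, :, 0, :]

        def backward(g, a=self, idx=idx):
            buf = np.zeros((n, lp, size, c))
            np.put_along_axis(buf, idx[:, :, None, :], g[:, :, None, :], axis=2)
            full = np.zeros_like(a.data)
            full[:, : lp * size, :] = buf.reshape(n, lp * size, c)
            a._accum(full)

        return Tensor._make(out, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS: graphs from 50-step BiLSTMs are deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tuple(tensors), offsets=offsets):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int) -> Tensor:
    def backward(g, ts=tuple(tensors)):
        for i, t in enumerate(ts):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)
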