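"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the compute substrate for the encoders, score networks and training
loops in this package.  It implements exactly the primitives those models
need: broadcasting arithmetic, batched matmul, reductions, elementwise
nonlinearities, indexing and concatenation, with gradients accumulated by a
topological backward sweep.  Everything runs in float64 on CPU; the models
here are desk-scale (molecules of a dozen atoms, widths of a few hundred),
where clarity and exact reproducibility matter more than throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
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

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g) if b.ndim == 2 else None
                if gb is None:
                    gb = a[:, None] * g[..., None, :]
                    gb = _unbroadcast(gb, b.shape)
                return _unbroadcast(ga, a.shape), gb
            if b.ndim == 1:
                ga = g[..., None] * b
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim == 2 else (a * g[..., None]).sum(
                    axis=tuple(range(a.ndim - 1))
                )
                return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            return (g * (s + self.data * s * (1.0 - s)),)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % len(shape) for a in axes)
                for a in sorted(axes):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis=None, keepdims: bool = False):
        # Used only for softmax shifting; gradient routed to first argmax.
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        return Tensor(out_data)  # detached by design

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    # -- backward -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            parent_grads = t._backward(g)
            for p, pg in zip(t._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
        # leaves visited but never reached carry zero gradient implicitly


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(out_data, tuple(tensors), backward)
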