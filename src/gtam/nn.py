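"""Neural-network layers and optimization on top of :mod:`gtam.autodiff`.

Layers follow the usual conventions: ``Linear`` with Glorot-uniform
initialization, ``LayerNorm`` with learned affine parameters, ``MLP`` as a
stack of Linear+activation.  Parameter initialization is driven by an
explicit :class:`numpy.random.Generator` so every model in the package is
reproducible from a named integer seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Embedding",
    "MLP",
    "Adam",
    "softmax",
    "log_softmax",
]


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> Iterator[Tensor]:
        seen = set()
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                if id(value) not in seen:
                    seen.add(id(value))
                    yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            bound = np.sqrt(6.0 / (d_in + d_out))
            w = rng.uniform(-bound, bound, size=(d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(n, d)), requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class MLP(Module):
    """Stack of ``n_layers`` Linear layers with SiLU between them."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, n_layers: int,
                 rng: np.random.Generator, zero_init_last: bool = False):
        dims = [d_in] + [d_hidden] * (n_layers - 1) + [d_out]
        self.layers = [
            Linear(dims[i], dims[i + 1], rng,
                   zero_init=(zero_init_last and i == n_layers - 1))
            for i in range(n_layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
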