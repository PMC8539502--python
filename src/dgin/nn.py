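"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for message-passing networks: dense matmul with bias,
elementwise arithmetic, ReLU/sigmoid, row gather, segment (scatter) sums and
concatenation, plus an Adam optimizer.  Gradients are accumulated by a
topological-order backward sweep over the recorded op graph.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (undo NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def identity(a) -> Tensor:
    return _as_tensor(a)


ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid, "identity": identity}


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def gather(a, index) -> Tensor:
    """Row gather: out[i] = a[index[i]]."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.int64)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, g)
        _accumulate(a, ga)

    return _make(a.data[index], (a,), backward)


def segment_sum(a, segment_ids, num_segments: int) -> Tensor:
    """out[s] = sum of rows of `a` whose segment id equals s."""
    a = _as_tensor(a)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out = np.zeros((num_segments,) + a.data.shape[1:])
    np.add.at(out, segment_ids, a.data)

    def backward(g):
        _accumulate(a, g[segment_ids])

    return _make(out, (a,), backward)


def tsum(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, np.broadcast_to(g, a.data.shape).astype(np.float64))

    return _make(a.data.sum(), (a,), backward)


def zeros_like(a: Tensor) -> Tensor:
    return Tensor(np.zeros_like(_as_tensor(a).data))


# ---------------------------------------------------------------------------
# Layers and optimization
# ---------------------------------------------------------------------------

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    """Dense map x @ W (+ b)."""

    def __init__(self, rng, in_dim: int, out_dim: int, bias: bool = True,
                 name: str = ""):
        self.W = Tensor(glorot(rng, in_dim, out_dim), requires_grad=True,
                        name=f"{name}.W")
        self.b = (Tensor(np.zeros(out_dim), requires_grad=True, name=f"{name}.b")
                  if bias else None)

    def __call__(self, x) -> Tensor:
        out = matmul(x, self.W)
        return add(out, self.b) if self.b is not None else out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Feed-forward stack: Linear -> act -> ... -> Linear (linear output)."""

    def __init__(self, rng, dims: list[int], activation: str = "relu",
                 name: str = ""):
        self.layers = [
            Linear(rng, dims[i], dims[i + 1], name=f"{name}.{i}")
            for i in range(len(dims) - 1)
        ]
        self.act = ACTIVATIONS[activation]

    def __call__(self, x) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = self.act(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
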