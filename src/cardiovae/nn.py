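"""Minimal reverse-mode automatic differentiation over numpy arrays.

A compact tape-based engine providing exactly the operations the point-cloud
VAE needs: (batched) matmul, broadcasting add/mul, relu, max-pooling over an
axis, concatenation, reshape, gather, and elementwise exp/square/sum.  All
arithmetic is float32 for throughput; gradients are accumulated in the same
dtype.  An Adam optimizer operates on a flat parameter dict.

The engine is deliberately small rather than general: every op it exposes is
exercised by the network and covered by finite-difference gradient checks in
the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = ["Tensor", "Parameter", "Adam", "linear", "concat", "gather",
           "max_pool_axis1", "relu"]


class Tensor:
    """Node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph execution ---------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None  # allocated lazily on first accumulation
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.bwd is not None and t.grad is not None:
                t.bwd(t.grad)

    # ---- operators ----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)

        def bwd(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, (self, other), bwd)

    def __sub__(self, other):
        other = _wrap(other)

        def bwd(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(-g, other.data.shape))

        return Tensor(self.data - other.data, (self, other), bwd)

    def __mul__(self, other):
        other = _wrap(other)

        def bwd(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, (self, other), bwd)

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _wrap(other)
        a, b = self.data, other.data

        def bwd(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            _accum(self, _unbroadcast(ga, a.shape))
            _accum(other, _unbroadcast(gb, b.shape))

        return Tensor(a @ b, (self, other), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            _accum(self, g.reshape(old))

        return Tensor(self.data.reshape(*shape), (self,), bwd)

    def sum(self):
        def bwd(g):
            _accum(self, np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(), (self,), bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            _accum(self, np.broadcast_to(g / n, self.data.shape))

        return Tensor(self.data.mean(), (self,), bwd)

    def square(self):
        def bwd(g):
            _accum(self, g * 2.0 * self.data)

        return Tensor(self.data**2, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            _accum(self, g * out_data)

        return Tensor(out_data, (self,), bwd)


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=DTYPE)
    else:
        t.grad += g


def _grad_buffer(t: Tensor):
    """Zero-initialised grad buffer for scatter-style backward passes."""
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    return t.grad


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def bwd(g):
        _accum(x, g * (out_data > 0))

    return Tensor(out_data, (x,), bwd)


def max_pool_axis1(x: Tensor) -> Tensor:
    """Max over axis 1 of a (B, N, D) tensor -> (B, D); symmetric pooling."""
    idx = np.argmax(x.data, axis=1)  # (B, D)
    b_idx = np.arange(x.data.shape[0])[:, None]
    d_idx = np.arange(x.data.shape[2])[None, :]

    def bwd(g):
        if x.requires_grad:
            np.add.at(_grad_buffer(x), (b_idx, idx, d_idx), g)

    return Tensor(x.data[b_idx, idx, d_idx], (x,), bwd)


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        ax = axis if axis >= 0 else g.ndim + axis
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[ax] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return Tensor(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def gather(x: Tensor, idx: np.ndarray, axis: int = 1) -> Tensor:
    """Index rows of a (B, N, D) tensor with per-batch indices (B, K)."""
    if axis != 1 or x.data.ndim != 3:
        raise NotImplementedError("gather supports axis=1 on 3-D tensors")
    b_idx = np.arange(x.data.shape[0])[:, None]

    def bwd(g):
        if x.requires_grad:
            np.add.at(_grad_buffer(x), (b_idx, idx), g)

    return Tensor(x.data[b_idx, idx], (x,), bwd)


def linear(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Fused affine map over the last axis (shared across leading axes)."""
    xd = x.data
    flat = xd.reshape(-1, xd.shape[-1])
    out = flat @ w.data
    out += b.data
    out = out.reshape(xd.shape[:-1] + (w.data.shape[1],))

    def bwd(g):
        gf = g.reshape(-1, g.shape[-1])
        _accum(w, flat.T @ gf)
        _accum(b, gf.sum(axis=0))
        if x.requires_grad:
            _accum(x, (gf @ w.data.T).reshape(xd.shape))

    return Tensor(out, (x, w, b), bwd)


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(DTYPE)


class Adam:
    """Adam optimizer over a dict of named Parameters."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.grad = None
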