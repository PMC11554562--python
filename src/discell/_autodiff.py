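"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the decoder, the attribute encoders and the
likelihoods need: broadcasting arithmetic, matmul, row gather (embedding
lookup), elementwise transcendentals including ``lgamma`` (whose gradient is
the digamma function), softplus/sigmoid/relu, and reductions.  Gradients are
accumulated into leaf tensors created with ``requires_grad=True``.

The engine is deliberately small: a ``Tensor`` wraps a float64 array plus a
closure that propagates the incoming cotangent to its parents; ``backward``
runs a topological sort.  All tests gradient-check it against central finite
differences.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import gammaln as _gammaln

__all__ = ["Tensor", "concat", "logsumexp", "Linear", "MLP", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _needs_graph(self, *others):
        return self.requires_grad or any(o.requires_grad for o in others)

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        if not self._needs_graph(other):
            return Tensor(out_data)
        a, b = self, other

        def bwd(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor(out_data, True, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        if not self.requires_grad:
            return Tensor(-self.data)
        return Tensor(-self.data, True, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        if not self._needs_graph(other):
            return Tensor(out_data)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return Tensor(out_data, True, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data
        if not self._needs_graph(other):
            return Tensor(out_data)
        a, b = self, other

        def bwd(g):
            return (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.shape),
            )

        return Tensor(out_data, True, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent
        if not self.requires_grad:
            return Tensor(out_data)
        a = self

        def bwd(g):
            return (g * exponent * a.data ** (exponent - 1),)

        return Tensor(out_data, True, (a,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data
        if not self._needs_graph(other):
            return Tensor(out_data)
        a, b = self, other

        def bwd(g):
            ga = g @ b.data.T if a.requires_grad or a._parents else None
            gb = a.data.T @ g if b.requires_grad or b._parents else None
            return ga, gb

        return Tensor(out_data, True, (a, b), bwd)

    # -- elementwise ----------------------------------------------------
    def _unary(self, out_data, dlocal):
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: (g * dlocal,))

    def exp(self):
        out = np.exp(self.data)
        return self._unary(out, out)

    def log(self):
        return self._unary(np.log(self.data), 1.0 / self.data)

    def log1p(self):
        return self._unary(np.log1p(self.data), 1.0 / (1.0 + self.data))

    def sqrt(self):
        out = np.sqrt(self.data)
        return self._unary(out, 0.5 / out)

    def tanh(self):
        out = np.tanh(self.data)
        return self._unary(out, 1.0 - out**2)

    def relu(self):
        return self._unary(np.maximum(self.data, 0.0), (self.data > 0).astype(np.float64))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.abs(self.data)))
        out = np.where(self.data >= 0, out, 1.0 - out)
        return self._unary(out, out * (1.0 - out))

    def softplus(self):
        # log(1 + e^x), computed stably for large |x|
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.abs(self.data)))
        sig = np.where(self.data >= 0, sig, 1.0 - sig)
        return self._unary(out, sig)

    def lgamma(self):
        return self._unary(_gammaln(self.data), _digamma(self.data))

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)
        a = self

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor(out_data, True, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        if not self.requires_grad:
            return Tensor(out_data)
        a = self
        return Tensor(out_data, True, (a,), lambda g: (g.reshape(a.shape),))

    def take_rows(self, index: np.ndarray):
        """Gather rows (embedding lookup); gradient scatter-adds."""
        index = np.asarray(index, dtype=np.intp)
        out_data = self.data[index]
        if not self.requires_grad:
            return Tensor(out_data)
        a = self

        def bwd(g):
            acc = np.zeros_like(a.data)
            np.add.at(acc, index, g)
            return (acc,)

        return Tensor(out_data, True, (a,), bwd)

    def mask(self, m: np.ndarray):
        """Multiply by a constant 0/1 mask (acts as `where`)."""
        return self * Tensor(np.asarray(m, dtype=np.float64))


def concat(tensors, axis=-1):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, True, tuple(tensors), bwd)


def logsumexp(t: Tensor, axis=-1, keepdims=False):
    shift = np.max(t.data, axis=axis, keepdims=True)  # constant w.r.t. grad
    shifted = t - Tensor(shift)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
    if not keepdims:
        out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
    return out


# ----------------------------------------------------------------------
# layers and optimizer
# ----------------------------------------------------------------------


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Fully connected network: ``depth`` hidden ReLU layers of ``width``.

    ``depth=0`` degenerates to a single affine map.
    """

    def __init__(self, n_in: int, n_out: int, depth: int, width: int, rng: np.random.Generator):
        self.layers = []
        d = n_in
        for _ in range(depth):
            self.layers.append(Linear(d, width, rng))
            d = width
        self.layers.append(Linear(d, n_out, rng))

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam with parameter groups (each group carries its own learning rate).

    Directly optimized embeddings typically want a higher rate than network
    weights, so groups are first-class.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8):
        # groups: list of (params, lr)
        self.groups = [(list(params), float(lr)) for params, lr in groups]
        self.state = {}
        self.t = 0

    def zero_grad(self):
        for params, _ in self.groups:
            for p in params:
                p.grad = None

    def step(self, betas=(0.9, 0.999), eps=1e-8):
        self.t += 1
        b1, b2 = betas
        for params, lr in self.groups:
            for p in params:
                if p.grad is None:
                    continue
                m, v = self.state.get(id(p), (np.zeros_like(p.data), np.zeros_like(p.data)))
                m = b1 * m + (1 - b1) * p.grad
                v = b2 * v + (1 - b2) * p.grad**2
                self.state[id(p)] = (m, v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + eps)
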