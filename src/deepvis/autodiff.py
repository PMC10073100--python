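"""Minimal vectorized reverse-mode automatic differentiation.

A small tape-based engine over numpy arrays, sized for the needs of this
package: dense layers, batch normalization, pairwise-distance matrices,
hyperbolic exponential maps and the similarity/loss algebra. Every public
op also accepts plain ndarrays (or scalars), in which case it evaluates
eagerly with numpy and returns an ndarray — this lets the similarity and
geometry code be written once and used both inside the training tape and
as ordinary numpy functions.

Gradients are accumulated by a topological backward sweep; broadcasting in
binary ops is handled by summing the upstream gradient over the broadcast
axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "is_tensor", "asarray",
    "exp", "log", "sqrt", "tanh", "cosh", "sinh", "arcosh",
    "clip", "power", "matmul", "tsum", "tmean", "concatenate",
    "leaky_relu", "where_positive",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn", "is_param", "name")

    def __init__(self, data, parents=(), grad_fn=None, is_param=False, name=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._grad_fn = grad_fn
        self.is_param = is_param
        self.name = name

    # -- introspection -------------------------------------------------
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

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, param={self.is_param})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._grad_fn(node.grad)):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy() if pgrad.base is not None else pgrad
                else:
                    parent.grad = parent.grad + pgrad

    def zero_grad(self):
        self.grad = None

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, x, y: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, x, y: (g, -g))

    def __rsub__(self, other):
        return _binary(_lift(other), self, np.subtract,
                       lambda g, x, y: (g, -g))

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, x, y: (g * y, g * x))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, x, y: (g / y, -g * x / (y * y)))

    def __rtruediv__(self, other):
        return _binary(_lift(other), self, np.divide,
                       lambda g, x, y: (g / y, -g * x / (y * y)))

    def __neg__(self):
        return _unary(self, np.negative, lambda g, x, out: -g)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        x = self

        def grad_fn(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor(x.data[idx], (x,), grad_fn)

    @property
    def T(self):
        x = self
        return Tensor(x.data.T, (x,), lambda g: (g.T,))

    def reshape(self, *shape):
        x = self
        orig = x.data.shape
        return Tensor(x.data.reshape(*shape), (x,),
                      lambda g: (g.reshape(orig),))


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def asarray(x):
    """Underlying ndarray of a Tensor, or the array itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _scalar_lift(x, ref: Tensor) -> Tensor:
    """Lift a non-Tensor operand; python scalars adopt the reference
    dtype so they do not promote float32 graphs to float64."""
    if np.isscalar(x):
        return Tensor(np.asarray(x, dtype=ref.data.dtype))
    return Tensor(np.asarray(x))


def _binary(a, b, fwd, bwd):
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return fwd(np.asarray(a), np.asarray(b))
    if isinstance(a, Tensor):
        a, b = a, (b if isinstance(b, Tensor) else _scalar_lift(b, a))
    else:
        a, b = _scalar_lift(a, b), b
    out = fwd(a.data, b.data)
    ad, bd = a.data, b.data

    def grad_fn(g):
        ga, gb = bwd(g, ad, bd)
        return (_unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape))

    return Tensor(out, (a, b), grad_fn)


def _unary(x, fwd, bwd):
    if not isinstance(x, Tensor):
        return fwd(np.asarray(x))
    out = fwd(x.data)
    xd = x.data
    return Tensor(out, (x,), lambda g: (bwd(g, xd, out),))


# -- elementwise ops ---------------------------------------------------

def exp(x):
    return _unary(x, np.exp, lambda g, xd, out: g * out)


def log(x):
    return _unary(x, np.log, lambda g, xd, out: g / xd)


def sqrt(x):
    return _unary(x, np.sqrt, lambda g, xd, out: g / (2.0 * out))


def tanh(x):
    return _unary(x, np.tanh, lambda g, xd, out: g * (1.0 - out * out))


def cosh(x):
    return _unary(x, np.cosh, lambda g, xd, out: g * np.sinh(xd))


def sinh(x):
    return _unary(x, np.sinh, lambda g, xd, out: g * np.cosh(xd))


def arcosh(x):
    """Inverse hyperbolic cosine; caller must keep the argument > 1."""
    return _unary(x, np.arccosh,
                  lambda g, xd, out: g / np.sqrt(xd * xd - 1.0))


def clip(x, lo, hi):
    """Clamp with pass-through gradient strictly inside [lo, hi]."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    out = np.clip(x.data, lo, hi)
    xd = x.data
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi

    def grad_fn(g):
        return (g * ((xd >= lo_) & (xd <= hi_)),)

    return Tensor(out, (x,), grad_fn)


def power(x, p):
    """x**p for scalar p (base must be positive unless p is an integer)."""
    return _unary(x, lambda d: np.power(d, p),
                  lambda g, xd, out: g * p * out / xd)


def leaky_relu(x, alpha=0.01):
    def fwd(d):
        return np.where(d > 0, d, alpha * d)

    return _unary(x, fwd,
                  lambda g, xd, out: g * np.where(xd > 0, 1.0, alpha))


def where_positive(cond, a, b):
    """Select a where cond > 0 else b; cond is a constant array."""
    cond = np.asarray(asarray(cond) > 0)
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.where(cond, a, b)
    a, b = _lift(a), _lift(b)
    out = np.where(cond, a.data, b.data)

    def grad_fn(g):
        return (_unbroadcast(g * cond, a.data.shape),
                _unbroadcast(g * ~cond, b.data.shape))

    return Tensor(out, (a, b), grad_fn)


# -- reductions and linear algebra ------------------------------------

def tsum(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)
    out = np.sum(x.data, axis=axis, keepdims=keepdims)
    shape = x.data.shape

    def grad_fn(g):
        if axis is None:
            return (np.broadcast_to(g, shape),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, shape),)

    return Tensor(out, (x,), grad_fn)


def tmean(x, axis=None, keepdims=False):
    n = asarray(x).size if axis is None else asarray(x).shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) / float(n)


def matmul(a, b):
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.asarray(a) @ np.asarray(b)
    a, b = _lift(a), _lift(b)
    out = a.data @ b.data
    ad, bd = a.data, b.data
    return Tensor(out, (a, b),
                  lambda g: (g @ bd.T, ad.T @ g))


def concatenate(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [_lift(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parts, grad_fn)
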