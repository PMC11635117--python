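"""Minimal vectorized reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the attention/routing/survival heads need:
elementwise arithmetic with broadcasting, matmul, tanh/sigmoid/relu/elu/exp/log,
reductions, softmax, concatenation and straight-through detachment. Functional
wrappers (:func:`tanh`, :func:`sigmoid`, ...) dispatch on input type so the same
forward code runs on plain ndarrays (inference, oracles) and on :class:`Tensor`
graphs (training).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tanh",
    "sigmoid",
    "relu",
    "elu",
    "exp",
    "log",
    "softmax",
    "concatenate",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in a dynamically built computation graph."""

    # make numpy defer binary ops to our reflected dunders
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=rg, _parents=parents if rg else (),
                      _backward=backward if rg else None)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()

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
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
            t.grad = t.grad + g
            if t._backward is not None:
                for p, pg in t._backward(g):
                    if not p.requires_grad:
                        continue
                    pg = _unbroadcast(pg, p.data.shape)
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other),
                         lambda g: [(self, g), (other, g)])
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        return self._make(self.data * other.data, (self, other),
                          lambda g: [(self, g * other.data), (other, g * self.data)])

    __rmul__ = __mul__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self._make(
            self.data / other.data, (self, other),
            lambda g: [(self, g / other.data),
                       (other, -g * self.data / other.data ** 2)])

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        return self._make(self.data ** p, (self,),
                          lambda g: [(self, g * p * self.data ** (p - 1))])

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def back(g):
            ad_, bd = a.data, b.data
            g = np.asarray(g)
            if ad_.ndim == 1 and bd.ndim == 1:      # inner product -> scalar
                ga, gb = g * bd, g * ad_
            elif bd.ndim == 1:                      # (..., n, k) @ (k,) -> (..., n)
                ga = g[..., None] * bd              # broadcast outer product
                gb = (ad_.reshape(-1, ad_.shape[-1]) * g.reshape(-1, 1)).sum(axis=0)
            elif ad_.ndim == 1:                     # (k,) @ (k, m) -> (m,)
                ga = bd @ g
                gb = np.outer(ad_, g)
            else:                                   # batched matrix product
                ga = g @ np.swapaxes(bd, -1, -2)
                gb = np.swapaxes(ad_, -1, -2) @ g
            return [(a, ga), (b, gb)]

        return self._make(a.data @ b.data, (a, b), back)

    def __rmatmul__(self, other):
        return self._lift(other) @ self

    def __getitem__(self, idx):
        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return [(self, out)]

        return self._make(self.data[idx], (self,), back)

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        return self._make(y, (self,), lambda g: [(self, g * (1 - y ** 2))])

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(y, (self,), lambda g: [(self, g * y * (1 - y))])

    def relu(self):
        m = self.data > 0
        return self._make(self.data * m, (self,), lambda g: [(self, g * m)])

    def elu(self, alpha: float = 1.0):
        x = self.data
        y = np.where(x > 0, x, alpha * (np.exp(np.minimum(x, 0)) - 1))
        d = np.where(x > 0, 1.0, y + alpha)
        return self._make(y, (self,), lambda g: [(self, g * d)])

    def exp(self):
        y = np.exp(self.data)
        return self._make(y, (self,), lambda g: [(self, g * y)])

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: [(self, g / self.data)])

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g, self.data.shape).copy())]

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: [(self, g.reshape(orig))])


# -- dispatched functional API ------------------------------------------------

def _dispatch(x, tensor_fn, np_fn):
    if isinstance(x, Tensor):
        return tensor_fn(x)
    return np_fn(np.asarray(x, dtype=np.float64))


def tanh(x):
    return _dispatch(x, Tensor.tanh, np.tanh)


def sigmoid(x):
    return _dispatch(x, Tensor.sigmoid,
                     lambda a: 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60))))


def relu(x):
    return _dispatch(x, Tensor.relu, lambda a: np.maximum(a, 0.0))


def elu(x, alpha: float = 1.0):
    if isinstance(x, Tensor):
        return x.elu(alpha)
    a = np.asarray(x, dtype=np.float64)
    return np.where(a > 0, a, alpha * (np.exp(np.minimum(a, 0)) - 1))


def exp(x):
    return _dispatch(x, Tensor.exp, np.exp)


def log(x):
    return _dispatch(x, Tensor.log, np.log)


def softmax(x, axis: int = -1):
    """Numerically stable softmax; the max-shift is treated as a constant."""
    if isinstance(x, Tensor):
        shift = np.max(x.data, axis=axis, keepdims=True)
        e = (x - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)
    a = np.asarray(x, dtype=np.float64)
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(parts, axis: int = 0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate([np.asarray(p, dtype=np.float64) for p in parts], axis=axis)
    parts = [Tensor._lift(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    data = np.concatenate([p.data for p in parts], axis=axis)

    def back(g):
        outs, start = [], 0
        for p, n in zip(parts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            outs.append((p, g[tuple(sl)]))
            start += n
        return outs

    rg = any(p.requires_grad for p in parts)
    return Tensor(data, requires_grad=rg, _parents=tuple(parts) if rg else (),
                  _backward=back if rg else None)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self._t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self._t)
            vhat = self._v[i] / (1 - self.b2 ** self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
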