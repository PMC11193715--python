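"""Minimal reverse-mode automatic differentiation and neural-network core.

Implements exactly the operations the heterogeneous-incomplete VAE needs:
broadcast-aware arithmetic, matmul, tanh/sigmoid/exp/log/softplus, reductions,
concatenation and slicing, plus dense layers, an LSTM cell unrolled over
visits, and an Adam optimiser.  Everything runs on plain numpy arrays; graphs
are built dynamically and freed after each backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Dense", "LSTM", "Adam", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the autodiff graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = True, prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------
    def _make(self, data, prev, backward):
        out = Tensor(data, prev=prev)
        out._backward = backward
        return out

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        return self + (-other)

    def __rsub__(self, other):
        return constant(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return constant(other) * self ** -1.0

    def __pow__(self, p: float):
        def backward(g, a=self):
            a._accum(g * p * a.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        def backward(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(np.clip(self.data, -700, 700))

        def backward(g, a=self, o=out_data):
            a._accum(g * o)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g * (1.0 - o * o))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def backward(g, a=self, o=out_data):
            a._accum(g * o * (1.0 - o))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            a._accum(g * 0.5 * (np.tanh(0.5 * a.data) + 1.0))

        return self._make(out_data, (self,), backward)

    # -- reductions, shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def reshape(self, *shape):
        def backward(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, i=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, i, g)
            a._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def log_softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        probs = np.exp(out_data)

        def backward(g, a=self, p=probs):
            a._accum(g - p * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        return self.log_softmax(axis=axis).exp()

    def cumsum(self, axis=-1):
        def backward(g, a=self):
            a._accum(np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis))

        return self._make(np.cumsum(self.data, axis=axis), (self,), backward)

    # -- autodiff driver --------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def constant(value) -> Tensor:
    """A tensor excluded from gradient accumulation."""
    return Tensor(value, requires_grad=False)


def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


Tensor.concat = staticmethod(concat)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Dense:
    """Affine layer `x @ W + b` with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class LSTM:
    """Single-layer LSTM unrolled over the visit axis.

    Input is a list of (N, n_in) tensors in chronological order; the final
    hidden state h_V (N, n_hidden) is returned as the sequence summary.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wx = Dense(n_in, 4 * n_hidden, rng)
        self.Wh = Dense(n_hidden, 4 * n_hidden, rng)
        # forget-gate bias starts at 1 so early training keeps memory open
        b = self.Wx.b.data
        b[n_hidden : 2 * n_hidden] = 1.0

    def __call__(self, steps) -> Tensor:
        n = steps[0].shape[0]
        H = self.n_hidden
        h = constant(np.zeros((n, H)))
        c = constant(np.zeros((n, H)))
        for x in steps:
            gates = self.Wx(x) + self.Wh(h)
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            o = gates[:, 2 * H : 3 * H].sigmoid()
            g = gates[:, 3 * H : 4 * H].tanh()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    @property
    def params(self):
        return self.Wx.params + self.Wh.params


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
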