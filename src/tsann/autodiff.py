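"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the network needs: broadcast arithmetic,
(batched) matrix multiplication, rectifier/logistic/log/sqrt nonlinearities,
axis reductions, softmax / log-softmax, reshape, transpose and concatenation.
Gradients are accumulated by a topological sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _wrap_like(self, other) -> "Tensor":
        """Wrap scalars at this tensor's dtype so float32 graphs stay float32."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:
            arr = arr.astype(self.data.dtype, copy=False)
        return Tensor(arr)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap_like(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap_like(other) + (-self)

    def __mul__(self, other):
        other = self._wrap_like(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap_like(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            # promote 1-D operands to matrices, then undo at the end;
            # skip the gradient of any operand that does not need one
            # (e.g. the large constant window tensors feeding the conv)
            a = self.data[None, :] if self.data.ndim == 1 else self.data
            b = other.data[:, None] if other.data.ndim == 1 else other.data
            gm = g
            if self.data.ndim == 1:
                gm = np.expand_dims(gm, -2)
            if other.data.ndim == 1:
                gm = np.expand_dims(gm, -1)
            ga = gb = None
            if self.requires_grad:
                if a.ndim == 2 and b.ndim > 2:
                    # batched rhs, 2-D lhs: one GEMM instead of batched + sum
                    m, n = gm.shape[-2], gm.shape[-1]
                    kk = b.shape[-2]
                    ga = np.einsum(
                        "bmn,bkn->mk", gm.reshape(-1, m, n), b.reshape(-1, kk, n)
                    )
                else:
                    ga = np.matmul(gm, np.swapaxes(b, -1, -2))
                if self.data.ndim == 1:
                    ga = np.squeeze(ga, axis=-2)
                    ga = ga.reshape((-1,) + self.data.shape).sum(axis=0)
                ga = _unbroadcast(ga, self.shape)
            if other.requires_grad:
                if b.ndim == 2 and a.ndim > 2:
                    # batched lhs, 2-D rhs (the Z @ W pattern): collapse the
                    # batch into one GEMM rather than writing a batched grad
                    k, n = a.shape[-1], gm.shape[-1]
                    gb = np.matmul(a.reshape(-1, k).T, gm.reshape(-1, n))
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), gm)
                if other.data.ndim == 1:
                    gb = np.squeeze(gb, axis=-1)
                    gb = gb.reshape((-1,) + other.data.shape).sum(axis=0)
                gb = _unbroadcast(gb, other.shape)
            return (ga, gb)

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def square(self):
        return self._make(self.data**2, (self,), lambda g: (2.0 * g * self.data,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- softmax family -------------------------------------------------------
    def softmax(self, axis=-1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def backward(g):
            return (g - sm * g.sum(axis=axis, keepdims=True),)

        return self._make(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return self._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    def expand_dims(self, axis):
        return self._make(np.expand_dims(self.data, axis), (self,), lambda g: (np.squeeze(g, axis=axis),))

    def __getitem__(self, idx):
        def backward(g):
            gg = np.zeros_like(self.data)
            np.add.at(gg, idx, g)
            return (gg,)

        return self._make(self.data[idx], (self,), backward)

    # -- engine ---------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # leaves visited inside the loop store into .grad; handle self-as-leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype)


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
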