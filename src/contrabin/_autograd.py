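"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the contrastive encoders need: affine
layers, LeakyReLU, dropout (as multiplication by a constant mask), row-wise
L2 normalization, concatenation, matrix products and the elementwise
exp/log/sum arithmetic of the NT-Xent loss. Gradients are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking arithmetic

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

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

    # -- operations --------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, out_data, dself, dother):
        other = Tensor._lift(other)
        out = Tensor(out_data, _prev=(self, other))

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(dself(g, other), self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(dother(g, other), other.data.shape))

        out._backward = backward
        return out

    def __add__(self, other):
        o = Tensor._lift(other)
        return self._binary(o, self.data + o.data,
                            lambda g, o: g, lambda g, o: g)

    __radd__ = __add__

    def __sub__(self, other):
        o = Tensor._lift(other)
        return self._binary(o, self.data - o.data,
                            lambda g, o: g, lambda g, o: -g)

    def __mul__(self, other):
        o = Tensor._lift(other)
        return self._binary(o, self.data * o.data,
                            lambda g, o: g * o.data, lambda g, o: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._lift(other)
        return self._binary(o, self.data / o.data,
                            lambda g, o: g / o.data,
                            lambda g, o: -g * self.data / (o.data ** 2))

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def matmul(self, other):
        o = Tensor._lift(other)
        out = Tensor(self.data @ o.data, _prev=(self, o))

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(g @ o.data.T)
            if o.requires_grad or o._prev:
                o._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    def transpose(self):
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    @property
    def T(self):
        return self.transpose()

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def leaky_relu(self, alpha: float = 0.01):
        mask = np.where(self.data > 0, 1.0, alpha)
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def l2_normalize_rows(self, eps: float = 1e-12):
        """y_i = x_i / ||x_i|| per row; the gradient removes the component
        of the upstream gradient parallel to y_i."""
        norms = np.linalg.norm(self.data, axis=1, keepdims=True)
        norms = np.maximum(norms, eps)
        y = self.data / norms
        out = Tensor(y, _prev=(self,))

        def backward(g):
            dot = np.sum(g * y, axis=1, keepdims=True)
            self._accumulate((g - y * dot) / norms)

        out._backward = backward
        return out

    @staticmethod
    def concat(tensors, axis=1):
        datas = [t.data for t in tensors]
        out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._prev:
                    t._accumulate(piece)

        out._backward = backward
        return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
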