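"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network is small enough (a few hundred thousand
parameters at desk scale) that a tensor-level tape with hand-written
vector-Jacobian products is fast and fully deterministic on CPU.  Every
primitive here is covered by central-difference gradient checks in the
test suite.

Conventions
-----------
* All data is ``float64``; oracle tests run at 1e-6..1e-8 tolerances.
* Broadcasting follows numpy; gradients of broadcast operands are summed
  back to the operand shape (:func:`_unbroadcast`).
* ``Tensor.backward()`` seeds the output gradient with ones and walks the
  tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "as_tensor", "Parameter", "SGD"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reversing numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum along axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
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

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._result(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self, p=p):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._result(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._result(np.matmul(self.data, other.data), (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return Tensor._result(np.transpose(self.data, axes), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        def backward(g, a=self, a1=a1, a2=a2):
            if a.requires_grad:
                a._accum(np.swapaxes(g, a1, a2))

        return Tensor._result(np.swapaxes(self.data, a1, a2), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * 0.5 / y)

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid

        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return Tensor._result(out_data, (self,), backward)

    def softplus(self):
        x = self.data
        out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

        def backward(g, a=self):
            if a.requires_grad:
                s = 0.5 * (1.0 + np.tanh(0.5 * a.data))
                a._accum(g * s)

        return Tensor._result(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))

        def backward(g, a=self, phi=phi):
            if a.requires_grad:
                x = a.data
                pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
                a._accum(g * (phi + x * pdf))

        return Tensor._result(x * phi, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, y=y, axis=axis):
            if a.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))

        return Tensor._result(y, (self,), backward)

    # -- structured ops -------------------------------------------------------
    def unfold2d(self, kernel: int, stride: int, padding: int):
        """Extract sliding ``kernel x kernel`` patches from a (B,H,W,C) grid.

        Returns a tensor of shape (B, Ho, Wo, kernel*kernel, C) where
        ``Ho = (H + 2*padding - kernel)//stride + 1``; zero padding.
        """
        b, h, w, c = self.data.shape
        ho = (h + 2 * padding - kernel) // stride + 1
        wo = (w + 2 * padding - kernel) // stride + 1
        xp = np.zeros((b, h + 2 * padding, w + 2 * padding, c), dtype=np.float64)
        xp[:, padding:padding + h, padding:padding + w, :] = self.data
        out_data = np.empty((b, ho, wo, kernel * kernel, c), dtype=np.float64)
        for i in range(kernel):
            for j in range(kernel):
                out_data[:, :, :, i * kernel + j, :] = xp[
                    :, i:i + stride * ho:stride, j:j + stride * wo:stride, :
                ]

        def backward(g, a=self, k=kernel, s=stride, p=padding, ho=ho, wo=wo):
            if not a.requires_grad:
                return
            b, h, w, c = a.data.shape
            gp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=np.float64)
            for i in range(k):
                for j in range(k):
                    gp[:, i:i + s * ho:s, j:j + s * wo:s, :] += g[:, :, :, i * k + j, :]
            a._accum(gp[:, p:p + h, p:p + w, :])

        return Tensor._result(out_data, (self,), backward)

    # -- tape ----------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    ``v <- momentum*v + grad + weight_decay*w``; ``w <- w - lr*v``.
    """

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
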