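"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a float64
ndarray and records, for every operation, a closure that maps the output
gradient back onto the operands.  All operations follow numpy broadcasting
semantics; gradients of broadcast operands are reduced back to the operand
shape.  The op set is exactly what the perturbation-response model needs
(matmul with batched broadcasting, elementwise arithmetic, tanh/relu/abs,
axis reductions, reshape/transpose, row gather, power with a constant
exponent).

Gradient correctness is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the context (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (shape of a broadcast result) back to ``shape``."""
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
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic properties -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._result(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.shape),
                    _unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g / b.data, a.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        # constant (non-Tensor) exponent only
        a = self
        e = float(exponent)

        def backward(g):
            return (g * e * a.data ** (e - 1.0),)

        return Tensor._result(a.data ** e, (a,), backward)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._result(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._result(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._result(out_data, (a,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._result(out_data, (a,), lambda g: (g * (1.0 - out_data ** 2),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._result(a.data * mask, (a,), lambda g: (g * mask,))

    def abs(self):
        a = self
        sgn = np.sign(a.data)
        return Tensor._result(np.abs(a.data), (a,), lambda g: (g * sgn,))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._result(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return a.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._result(a.data.reshape(shape), (a,),
                              lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._result(a.data.transpose(axes), (a,),
                              lambda g: (g.transpose(inv),))

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._result(a.data.swapaxes(ax1, ax2), (a,),
                              lambda g: (g.swapaxes(ax1, ax2),))

    def take_rows(self, indices):
        """Gather rows along axis 0; backward scatter-adds."""
        a = self
        idx = np.asarray(indices, dtype=np.intp)

        def backward(g):
            out = np.zeros(a.shape)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._result(a.data[idx], (a,), backward)

    # -- matmul ---------------------------------------------------------------

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires tensors with ndim >= 2")

        def backward(g):
            ga = g @ b.data.swapaxes(-1, -2)
            gb = a.data.swapaxes(-1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._result(a.data @ b.data, (a, b), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64, copy=True)
                else:
                    parent.grad += g


def parameter(data, rng=None, shape=None, scale=None) -> Tensor:
    """Create a trainable leaf tensor.

    Either pass ``data`` directly, or pass ``data=None`` with ``rng``,
    ``shape`` and ``scale`` to draw N(0, scale^2) entries.
    """
    if data is None:
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(np.array(data, dtype=np.float64, copy=True), requires_grad=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max shift is detached)."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Standard Adam optimizer over a list of leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
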