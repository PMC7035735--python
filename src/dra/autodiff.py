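"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training machinery in this package (ZINB reconstruction likelihood,
adversarial objectives, gradient penalty) needs gradients of scalar losses
with respect to network parameters, and — for the gradient-penalty critic —
gradients of gradients (double backprop). This module provides a small
``Tensor`` type that records a computation graph and supports both.

Every vector-Jacobian product is itself expressed in ``Tensor`` operations,
so calling :func:`grad` with ``create_graph=True`` yields gradients that are
themselves differentiable. Data are float64 throughout; the package favours
reproducibility over speed and all arrays involved are small.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "as_tensor", "grad", "lgamma", "clip", "leaky_relu", "sigmoid"]


class Tensor:
    """A numpy array with an attached backward graph.

    Parameters
    ----------
    data:
        Array-like; stored as float64.
    requires_grad:
        Mark this tensor as a differentiation leaf (e.g. a network weight).
    """

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: Tensor | None = None
        self._parents = _parents
        self._vjps = _vjps

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g * other, self.shape),
                lambda g: _unbroadcast(g * self, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(
            self.data ** p,
            _parents=(self,),
            _vjps=(lambda g: g * (float(p) * self ** (p - 1.0)),),
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.ndim == 1 and other.ndim == 1:
            return (self * other).sum()
        if other.ndim == 1:
            return (self @ other.reshape(-1, 1)).reshape(self.shape[:-1])
        if self.ndim == 1:
            return (self.reshape(1, -1) @ other).reshape((other.shape[-1],))
        return Tensor(
            self.data @ other.data,
            _parents=(self, other),
            _vjps=(
                lambda g: g @ other.transpose(),
                lambda g: self.transpose() @ g,
            ),
        )

    # ------------------------------------------------------------- reshaping
    def transpose(self) -> "Tensor":
        return Tensor(
            self.data.T,
            _parents=(self,),
            _vjps=(lambda g: g.transpose(),),
        )

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _vjps=(lambda g: g.reshape(old),),
        )

    def broadcast_to(self, shape) -> "Tensor":
        return Tensor(
            np.broadcast_to(self.data, shape),
            _parents=(self,),
            _vjps=(lambda g: _unbroadcast(g, self.shape),),
        )

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        def vjp(g):
            gd = g
            if not keepdims and axis is not None:
                kshape = list(in_shape)
                for ax in np.atleast_1d(axis):
                    kshape[ax] = 1
                gd = gd.reshape(tuple(kshape))
            return gd.broadcast_to(in_shape)

        return Tensor(out_data, _parents=(self,), _vjps=(vjp,))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,), _vjps=())
        out._vjps = (lambda g: g * out,)
        return out

    def log(self) -> "Tensor":
        return Tensor(
            np.log(self.data),
            _parents=(self,),
            _vjps=(lambda g: g / self,),
        )

    def sqrt(self) -> "Tensor":
        return self ** 0.5


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    # sum over prepended axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape) if g.shape != tuple(shape) else g


# --------------------------------------------------------------- functions
def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(_sp.expit(x.data), _parents=(x,), _vjps=())
    out._vjps = (lambda g: g * out * (1.0 - out),)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = np.where(x.data > 0.0, 1.0, slope)
    return Tensor(x.data * mask, _parents=(x,), _vjps=(lambda g: g * Tensor(mask),))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through zero gradient outside the interval."""
    x = as_tensor(x)
    mask = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
    return Tensor(
        np.clip(x.data, lo, hi), _parents=(x,), _vjps=(lambda g: g * Tensor(mask),)
    )


def lgamma(x: Tensor) -> Tensor:
    """Log-gamma; its gradient uses the digamma function.

    The digamma factor is treated as a constant of the backward pass, so
    second derivatives through ``lgamma`` are not supported (never needed
    here: the ZINB likelihood only requires first-order gradients).
    """
    x = as_tensor(x)
    return Tensor(
        _sp.gammaln(x.data),
        _parents=(x,),
        _vjps=(lambda g: g * Tensor(_sp.digamma(x.data)),),
    )


# ----------------------------------------------------------------- backward
def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def _backward_pass(out: Tensor, seed: Tensor, create_graph: bool):
    grads: dict[int, Tensor] = {id(out): seed}
    order = _toposort(out)
    for node in reversed(order):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            if not create_graph:
                pg = pg.detach()
            prev = grads.get(id(parent))
            grads[id(parent)] = pg if prev is None else prev + pg
    return grads, order


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graphs
    and can be differentiated again (used by the gradient penalty).
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    seed = Tensor(np.ones_like(output.data))
    grads, _ = _backward_pass(output, seed, create_graph)
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out[0] if single else out


def backward(output: Tensor) -> None:
    """Accumulate ``.grad`` on every requires-grad leaf below ``output``."""
    if output.data.size != 1:
        raise ValueError("backward() requires a scalar output")
    grads, order = _backward_pass(output, Tensor(np.ones_like(output.data)), False)
    for node in order:
        if not node._parents and node.requires_grad:
            g = grads.get(id(node))
            if g is not None:
                node.grad = g if node.grad is None else node.grad + g


Tensor.backward = backward
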