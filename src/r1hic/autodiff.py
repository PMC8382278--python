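"""Vectorized reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every upstream tensor created with ``requires_grad=True``.  The operation
set is deliberately small — elementwise arithmetic, matmul, shape surgery
(reshape / transpose / slicing / padding / concatenation), reductions and the
handful of nonlinearities the network blocks need — which keeps every gradient
closed-form and easy to verify by finite differences.

All computation is float64 and single-threaded numpy, so repeated runs with
identical inputs are bit-for-bit reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "Parameter", "astensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over dims that were stretched from 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
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

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(
            self.data**e,
            (self,),
            lambda g: (g * e * self.data ** (e - 1.0),),
        )

    def __matmul__(self, other):
        other = astensor(other)
        out = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            if self.data.ndim == 1:  # vector @ matrix
                ga = g @ other.data.T if other.data.ndim == 2 else ga
            return (
                _unbroadcast(ga.reshape(ga.shape), self.shape)
                if ga.shape != self.shape
                else ga,
                _unbroadcast(gb, other.shape) if gb.shape != other.shape else gb,
            )

        return Tensor._make(out, (self, other), backward)

    # -- shape surgery --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad2d(self, pad: int, axes: tuple[int, int] = (-3, -2)):
        """Zero-pad `pad` entries on both sides of two axes (default H, W of
        a channels-last tensor)."""
        width = [(0, 0)] * self.ndim
        ax = [a % self.ndim for a in axes]
        for a in ax:
            width[a] = (pad, pad)
        sl = tuple(
            slice(pad, -pad) if i in ax and pad else slice(None)
            for i in range(self.ndim)
        )
        return Tensor._make(
            np.pad(self.data, width), (self,), lambda g: (g[sl],)
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            expanded = out if keepdims else np.expand_dims(out, axis)
            mask = self.data == expanded
            # split gradient across ties to keep the estimator unbiased
            mask = mask / mask.sum(axis=axis, keepdims=True)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (mask * g,)

        return Tensor._make(out, (self,), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(
            self.data * factor, (self,), lambda g: (g * factor,)
        )

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def softplus(self):
        out = np.logaddexp(0.0, self.data)
        sig = expit(self.data)
        return Tensor._make(out, (self,), lambda g: (g * sig,))

    def sigmoid(self):
        # clip keeps the output strictly inside (0, 1) in float64
        out = expit(np.clip(self.data, -500, 500))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: (g / self.data,)
        )

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped entries only."""
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    ndim = tensors[0].ndim
    ax = axis % ndim

    def backward(g):
        return tuple(
            g[
                tuple(
                    slice(offsets[i], offsets[i + 1]) if d == ax else slice(None)
                    for d in range(ndim)
                )
            ]
            for i in range(len(tensors))
        )

    return Tensor._make(out, tuple(tensors), backward)
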