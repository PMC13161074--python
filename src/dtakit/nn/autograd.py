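"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the affinity model needs: broadcasted
arithmetic, batched matmul, softmax, embedding lookup, slicing/padding
(for the convolutional encoders), reshape/transpose and reductions.
Gradients are accumulated in float64 ndarrays; the graph is a DAG of
:class:`Tensor` nodes freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._from_op(
            self.data + o.data,
            (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._from_op(
            self.data * o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.shape),
                _unbroadcast(g * self.data, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._from_op(
            self.data / o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.shape),
                _unbroadcast(-g * self.data / (o.data**2), o.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor._from_op(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    def __matmul__(self, other):
        o = self._coerce(other)
        a, b = self.data, o.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._from_op(a @ b, (self, o), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._from_op(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis (used by 'same' convolutions)."""
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        slicer = [slice(None)] * self.ndim
        n = self.shape[axis]
        slicer[axis] = slice(before, before + n)
        slicer = tuple(slicer)
        return Tensor._from_op(
            np.pad(self.data, widths), (self,), lambda g: (g[slicer],)
        )

    # -- softmax (primitive: stable, with exact zeros for -inf surrogates) ----
    def softmax(self, axis: int = -1):
        x = self.data
        out_data = np.exp(x - x.max(axis=axis, keepdims=True))
        out_data = out_data / out_data.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((g - dot) * out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- embedding lookup ------------------------------------------------------
    def take_rows(self, indices: np.ndarray):
        """Gather rows of a (V, h) table by an integer index array."""
        indices = np.asarray(indices)
        V = self.shape[0]

        def backward(g):
            flat_idx = indices.reshape(-1)
            flat_g = g.reshape(-1, self.shape[-1])
            # scatter-add via bincount per column: much faster than ufunc.at
            full = np.empty_like(self.data)
            for col in range(self.shape[-1]):
                full[:, col] = np.bincount(flat_idx, weights=flat_g[:, col],
                                           minlength=V)
            return (full,)

        return Tensor._from_op(self.data[indices], (self,), backward)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer; carries a name for grouping."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._from_op(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
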