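"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations the package's networks need:
broadcasting arithmetic, matmul, reductions, reshapes, concatenation,
slicing, a numerically stable softmax / log-softmax, and ELU.  Gradients
are accumulated in float64.  Convolution and pooling primitives live in
:mod:`gdtil.nn.functional` as dedicated ops with hand-written adjoints.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._children = tuple(_children)
        self._backward = _backward

    # -- graph bookkeeping ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        """Return a view of the data cut out of the autodiff graph."""
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order walk -> topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        work: list[tuple[Tensor, bool]] = [(self, False)]
        while work:
            node, done = work.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            work.append((node, True))
            for c in node._children:
                work.append((c, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, children, backward) -> "Tensor":
        req = any(c.requires_grad for c in children)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _children=[c for c in children if c.requires_grad], _backward=backward)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), bwd)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bwd(g):
            self._accumulate(g * np.where(pos, 1.0, out_data + alpha))

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.shape

        def bwd(g):
            self._accumulate(g.reshape(src_shape))

        return self._make(out_data, (self,), bwd)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return self._make(out_data, (self,), bwd)

    def pad_last(self, left: int, right: int):
        """Zero-pad the trailing axis."""
        pad = [(0, 0)] * (self.ndim - 1) + [(left, right)]
        out_data = np.pad(self.data, pad)
        n = self.shape[-1]

        def bwd(g):
            sl = [slice(None)] * (self.ndim - 1) + [slice(left, left + n)]
            self._accumulate(g[tuple(sl)])

        return self._make(out_data, (self,), bwd)

    # -- softmax family --------------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), bwd)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bwd(g):
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), bwd)


class Parameter(Tensor):
    """A trainable tensor tagged with a block name for the freezing policy."""

    __slots__ = ("name", "block", "trainable")

    def __init__(self, data, name: str = "", block: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.block = block
        self.trainable = True


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(out_data, tensors, bwd)
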