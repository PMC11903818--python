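"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed for a convolutional
encoder-decoder with masked global pooling: broadcast arithmetic, matmul
against 2-D weight matrices, shape ops, zero-padding, im2col patch
extraction, 2x2 max pooling, channel concatenation, and the pointwise
nonlinearities relu / sigmoid / log / hard clip to [0, 1].

Gradients flow through a tape built implicitly by the ``Tensor`` graph and
are accumulated by :meth:`Tensor.backward` in reverse topological order.
All arrays are float32 unless the caller supplies float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "patches", "pad2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    #: make numpy defer to the reflected operators instead of broadcasting
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype != np.float64 else np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_owned = False

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is stored by reference (cheap); a second one
        # allocates a fresh owned buffer so shared views are never mutated
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
            self.grad = grad
            self._grad_owned = False
        elif not self._grad_owned:
            self.grad = self.grad + grad
            self._grad_owned = True
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return self._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        """Matmul of (..., m, k) against a strictly 2-D (k, n) weight."""
        other = self._lift(other)
        if other.data.ndim != 2:
            raise ValueError("matmul rhs must be 2-D")

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                k = a.data.shape[-1]
                b._accum(a.data.reshape(-1, k).T @ g.reshape(-1, b.data.shape[1]))

        return self._node(self.data @ other.data, (self, other), bwd)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(g, a=self):
            a._accum(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g, a=self):
            a._accum(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).astype(a.data.dtype))

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            a._accum(g * m)

        return self._node(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.1):
        """max(x, slope*x); the nonzero negative slope prevents permanently
        dead units under aggressive optimizer steps."""
        mask = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)

        def bwd(g, a=self, m=mask):
            a._accum(g * m)

        return self._node(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bwd(g, a=self, o=out):
            a._accum(g * o * (1.0 - o))

        return self._node(out, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)

        return self._node(np.log(self.data), (self,), bwd)

    def clip01(self):
        """Hard clip to [0, 1]; subgradient zero outside the open interval."""
        mask = (self.data > 0.0) & (self.data < 1.0)

        def bwd(g, a=self, m=mask):
            a._accum(g * m)

        return self._node(np.clip(self.data, 0.0, 1.0), (self,), bwd)

    # -- pooling -----------------------------------------------------------
    def max(self, axis: int):
        """Max over one axis (removed); ties route the gradient to the first max."""
        idx = self.data.argmax(axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def bwd(g, a=self, idx=idx, axis=axis):
            gr = np.zeros(a.shape, dtype=g.dtype)
            np.put_along_axis(gr, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            a._accum(gr)

        return self._node(np.squeeze(out, axis=axis), (self,), bwd)

    def maxpool2(self):
        """2x2 max pooling on NHWC."""
        n, h, w, c = self.shape
        r = self.reshape(n, h // 2, 2, w // 2, 2, c)
        return r.max(axis=4).max(axis=2)


def pad2d(x: Tensor, p: int) -> Tensor:
    """Zero-pad the two spatial axes of an NHWC tensor by ``p``."""

    def bwd(g, a=x, p=p):
        a._accum(g[:, p:-p, p:-p, :])

    out = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    return Tensor._node(out, (x,), bwd)


def patches(x: Tensor, k: int) -> Tensor:
    """im2col: extract all k x k patches of an NHWC tensor (valid positions).

    Returns shape (N, H-k+1, W-k+1, k*k*C).  Both directions are built from
    k*k shifted views, so no scatter indexing is needed.
    """
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    out = np.empty((n, oh, ow, k * k, c), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, :, i * k + j, :] = x.data[:, i:i + oh, j:j + ow, :]
    out = out.reshape(n, oh, ow, k * k * c)

    def bwd(g, a=x, n=n, oh=oh, ow=ow, k=k, c=c):
        g = g.reshape(n, oh, ow, k * k, c)
        gx = np.zeros(a.shape, dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, i:i + oh, j:j + ow, :] += g[:, :, :, i * k + j, :]
        a._accum(gx)

    return Tensor._node(out, (x,), bwd)


def concat(a: Tensor, b: Tensor, axis: int = -1) -> Tensor:
    na = a.shape[axis]

    def bwd(g, a=a, b=b, axis=axis, na=na):
        ga, gb = np.split(g, [na], axis=axis)
        if a.requires_grad:
            a._accum(ga)
        if b.requires_grad:
            b._accum(gb)

    return Tensor._node(np.concatenate([a.data, b.data], axis=axis), (a, b), bwd)
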