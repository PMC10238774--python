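"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The quaternion layers need trainable convolutions, batch normalisation and
attention gates; this module provides the small tape-based engine they are
built on.  A :class:`Tensor` wraps an ``ndarray``, records the operations
applied to it, and :meth:`Tensor.backward` accumulates gradients by reverse
topological traversal.  Only the primitives the network uses are
implemented; every backward rule is exercised by finite-difference checks
in the test suite.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "structured_expand", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * (other ** -1.0)
        return self * (1.0 / other)

    def __rtruediv__(self, other):
        return Tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        # numerically stable two-branch logistic
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, 0, None))),
                            np.exp(np.clip(x, None, 0))
                            / (1.0 + np.exp(np.clip(x, None, 0))))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; gradient flows to the first arg-max."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = self.data.argmax(axis=axis)

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims and g.ndim == out_data.ndim:
                gexp = np.expand_dims(g, axis)
            else:
                gexp = g
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis),
                              np.asarray(gexp), axis)
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bw)


def structured_expand(w: Tensor, mixing: np.ndarray) -> Tensor:
    """Expand per-pair component weights into a structured real kernel.

    ``w`` has shape ``(O, I, ..., C)`` holding ``C`` components per
    (output, input) pair; ``mixing`` has shape ``(A, B, C)`` with entries in
    {-1, 0, +1} and defines the ``A x B`` real block each component vector
    expands to.  Output shape: ``(A*O, B*I, ...)``.  This is how a
    quaternion weight becomes the equivalent real convolution kernel.
    """
    A, B, C = mixing.shape
    O, I = w.shape[0], w.shape[1]
    spatial = w.shape[2:-1]
    out_data = np.einsum("abc,oi...c->oaib...", mixing, w.data)
    out_data = out_data.reshape((A * O, B * I) + spatial)

    def bw(g):
        if w.requires_grad:
            gr = g.reshape((O, A, I, B) + spatial)
            w._accumulate(np.einsum("abc,oaib...->oi...c", mixing, gr))

    return Tensor._make(out_data, (w,), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: tuple[int, int] = (1, 1),
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col + GEMM.

    ``x``: (B, C_in, H, W); ``w``: (C_out, C_in, kh, kw); ``b``: (C_out,).
    The column matrix built in the forward pass is cached and reused for
    the weight gradient; the input gradient is scattered back with one
    strided addition per kernel tap (col2im).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    sh, sw = stride
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    kh, kw = w.shape[2], w.shape[3]
    co = w.shape[0]
    bsz = x.shape[0]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    ho, wo = win.shape[2], win.shape[3]
    # columns: (B*Ho*Wo, C*kh*kw), contiguous once
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        bsz * ho * wo, -1)
    w_mat = w.data.reshape(co, -1)
    out_data = (cols @ w_mat.T).reshape(bsz, ho, wo, co).transpose(0, 3, 1, 2)
    out_data = np.ascontiguousarray(out_data)
    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
        if w.requires_grad:
            w._accumulate((g_mat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcol = (g_mat @ w_mat).reshape(bsz, ho, wo, -1, kh, kw)
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u:u + sh * ho:sh, v:v + sw * wo:sw] += \
                        gcol[:, :, :, :, u, v].transpose(0, 3, 1, 2)
            hp, wp = xp.shape[2], xp.shape[3]
            gx = gxp[:, :, ph:hp - ph, pw:wp - pw] if (ph or pw) else gxp
            x._accumulate(np.ascontiguousarray(gx))

    return Tensor._make(out_data, parents, bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable).

    ``loss_i = max(z,0) - z*y + log(1 + exp(-|z|))``; optional per-sample
    weights rescale each term before averaging.  Exact closed-form gradient
    ``(sigmoid(z) - y) * w / n``.
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=z.dtype)
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray((per * w).mean())

    def bw(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (p - y) * w / z.size)

    return Tensor._make(out_data, (logits,), bw)
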