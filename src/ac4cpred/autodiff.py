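"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the ac4C network needs: broadcasting
arithmetic, matmul (optionally batched), shape ops, ReLU/sigmoid/exp/log/pow,
axis reductions, concatenation, embedding lookup, and a dilated 1-D
convolution with "same" or causal zero-padding. Gradients accumulate into
``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar loss.

Arrays are kept in float32 for speed; gradient checks in the test-suite run
the same graph in float64.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "embedding_lookup", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward
        self._grad_shared = False

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph mechanics ----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        # copy-on-write: the first contribution is stored by reference (it may
        # alias another tensor's grad); a second contribution allocates
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
            shared = False
        else:
            shared = True
        if self.grad is None:
            self.grad = g
            self._grad_shared = shared
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data)
        self._grad_shared = False
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar path: preserves dtype
            out = Tensor(self.data + other, parents=(self,))

            def backward_s(g):
                if self.requires_grad:
                    self._accumulate(g)

            out._backward = backward_s
            return out
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._lift(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # scalar path: preserves dtype
            out = Tensor(self.data * other, parents=(self,))

            def backward_s(g):
                if self.requires_grad:
                    self._accumulate(g * other)

            out._backward = backward_s
            return out
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- nonlinearities -----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward = backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        """Basic (non-repeating) slicing with gradient scatter."""
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                gx[idx] += g
                self._accumulate(gx)

        out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        src_shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, src_shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % len(src_shape) for a in axes))
            self._accumulate(np.broadcast_to(g, src_shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax along ``axis`` (fused primitive)."""
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    a = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(a, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(a * (g - (g * a).sum(axis=axis, keepdims=True)))

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def embedding_lookup(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of ``weight`` (V, d) by an integer array of any shape."""
    indices = np.asarray(indices)
    out = Tensor(weight.data[indices], parents=(weight,))

    def backward(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, indices, g)
            weight._accumulate(gw)

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1,
           padding: str = "same") -> Tensor:
    """Dilated 1-D convolution (cross-correlation) with zero padding.

    Parameters
    ----------
    x : Tensor, shape (N, C_in, L)
    w : Tensor, shape (C_out, C_in, k)
    b : Tensor of shape (C_out,) or None
    dilation : tap spacing ``d``; output t sums w_i * x[t + d*i - offset]
    padding : "same" (centered) or "causal" (output t sees inputs <= t only)
    """
    if x.ndim != 3 or w.ndim != 3:
        raise ValueError("conv1d expects x (N,C,L) and w (C_out,C_in,k)")
    n, c_in, length = x.shape
    c_out, c_in_w, k = w.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input has {c_in}, kernel expects {c_in_w}")
    span = (k - 1) * dilation + 1
    if padding == "causal":
        left, right = span - 1, 0
    elif padding == "same":
        left = (span - 1) // 2
        right = span - 1 - left
    else:
        raise ValueError(f"unknown padding {padding!r}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right)))
    # cols[..., i] is the input slice aligned with kernel tap i
    cols = np.stack([xp[:, :, i * dilation: i * dilation + length] for i in range(k)], axis=-1)
    # (N, L, C_in*k) @ (C_in*k, C_out)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(n, length, c_in * k)
    w2 = w.data.reshape(c_out, c_in * k)
    y = cols2 @ w2.T
    if b is not None:
        y = y + b.data[None, None, :]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y.transpose(0, 2, 1), parents=parents)

    def backward(g):
        gy = g.transpose(0, 2, 1)  # (N, L, C_out)
        if w.requires_grad:
            gw2 = np.tensordot(gy, cols2, axes=([0, 1], [0, 1])).astype(w.data.dtype)
            w._accumulate(gw2.reshape(c_out, c_in, k))
        if b is not None and b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 1)).astype(b.data.dtype))
        if x.requires_grad:
            gcols2 = gy @ w2  # (N, L, C_in*k)
            gcols = gcols2.reshape(n, length, c_in, k).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[:, :, i * dilation: i * dilation + length] += gcols[:, :, :, i]
            x._accumulate(gxp[:, :, left: left + length])

    out._backward = backward
    return out
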