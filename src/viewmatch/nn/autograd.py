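"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only what the mini networks need: broadcasting elementwise arithmetic,
matmul, a strided 2-D convolution, shape ops, the usual nonlinearities and
reductions.  Everything is float64 and fully deterministic, which keeps
training runs reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "logsumexp", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, prev: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (
                (_unbroadcast(g, self.shape), self),
                (_unbroadcast(g, other.shape), other),
            )

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                (_unbroadcast(g * other.data, self.shape), self),
                (_unbroadcast(g * self.data, other.shape), other),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                (_unbroadcast(g / other.data, self.shape), self),
                (_unbroadcast(-g * self.data / other.data**2, other.shape), other),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return ((g * p * self.data ** (p - 1), self),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                (_unbroadcast(ga, self.shape), self),
                (_unbroadcast(gb, other.shape), other),
            )

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: ((g * mask, self),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: ((g * s * (1 - s), self),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: ((g * (1 - t**2), self),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: ((g * e, self),))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: ((g / self.data, self),))

    # -- reductions / shape --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((np.broadcast_to(g, self.shape).copy(), self),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: ((g.reshape(old), self),)
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: ((g.transpose(inv), self),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((full, self),)

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff ------------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for child_grad, child in node._backward(g):
                    if not child.requires_grad:
                        continue
                    if id(child) in grads:
                        grads[id(child)] += child_grad
                    else:
                        grads[id(child)] = child_grad

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((p, t) for p, t in zip(parts, tensors))

    return Tensor._make(out_data, tuple(tensors), backward)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (keeps gradient flow)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis).log() + Tensor(np.squeeze(m, axis=axis))
    return out


# -- convolution -------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, oh, ow, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * k * k)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """Valid-mode strided convolution (no padding).

    ``x`` is (N, C, H, W); ``weight`` is (F, C, k, k); ``bias`` is (F,).
    Returns (N, F, oh, ow).
    """
    n, c, h, w = x.shape
    f, c2, k, _ = weight.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    patches = _im2col(x.data, k, stride)  # (N, oh, ow, C*k*k)
    wmat = weight.data.reshape(f, -1)
    out_data = patches @ wmat.T + bias.data  # (N, oh, ow, F)
    out_data = out_data.transpose(0, 3, 1, 2)
    oh, ow = out_data.shape[2], out_data.shape[3]

    def backward(g):
        gt = g.transpose(0, 2, 3, 1)  # (N, oh, ow, F)
        gw = np.tensordot(gt, patches, axes=([0, 1, 2], [0, 1, 2])).reshape(weight.shape)
        gb = gt.sum(axis=(0, 1, 2))
        gpatches = gt @ wmat  # (N, oh, ow, C*k*k)
        gpatches = gpatches.reshape(n, oh, ow, c, k, k)
        gx = np.zeros_like(x.data)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + oh * stride : stride, dj : dj + ow * stride : stride] += (
                    gpatches[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                )
        return ((gx, x), (gw, weight), (gb, bias))

    return Tensor._make(out_data, (x, weight, bias), backward)
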