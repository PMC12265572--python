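"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides the differentiable substrate for the foreground-aware
loss terms and the small 3D encoder--decoder backbone.  It is deliberately
tiny: a tape-based :class:`Tensor` supporting broadcasting arithmetic,
elementwise nonlinearities, reductions, and the three structured ops a
shape-preserving 3D U-net needs (same-padded 3D convolution, 2x average
pooling, 2x nearest-neighbour upsampling).

Gradients are accumulated in float64.  All ops are pure numpy; there is no
device or dtype negotiation.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor", "conv3d", "avg_pool3d", "upsample_nearest3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape.

    Parameters
    ----------
    data:
        Array-like payload; converted to float64.
    requires_grad:
        Whether backward() should accumulate a gradient here.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | float | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        grad = np.broadcast_to(np.asarray(grad, dtype=np.float64), self.data.shape)

        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.array(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        out_data = self.data**exponent

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def abs(self) -> "Tensor":
        """|x|; subgradient 0 at x=0."""

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * np.sign(self.data))

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bw)

    __abs__ = abs

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes through where strictly inside bounds."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g: np.ndarray) -> None:
            self._accumulate(g * inside)

        return Tensor(np.clip(self.data, lo, hi), _parents=(self,), _backward=bw)

    # -- reductions -------------------------------------------------------

    def sum(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(self.data.sum(), _parents=(self,), _backward=bw)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bw(g: np.ndarray) -> None:
            self._accumulate(np.broadcast_to(g / n, self.shape).copy())

        return Tensor(self.data.mean(), _parents=(self,), _backward=bw)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape

        def bw(g: np.ndarray) -> None:
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- structured ops for the 3D backbone -----------------------------------


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded 3D convolution (cross-correlation).

    x: (N, C_in, Z, Y, X); weight: (C_out, C_in, kz, ky, kx), odd kernel;
    bias: (C_out,).  Output: (N, C_out, Z, Y, X).
    """
    kz, ky, kx = weight.shape[2:]
    pz, py, px = kz // 2, ky // 2, kx // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
    # windows: (N, C_in, Z, Y, X, kz, ky, kx)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))
    out = np.tensordot(win, weight.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    # out: (N, Z, Y, X, C_out) -> (N, C_out, Z, Y, X)
    out = np.moveaxis(out, -1, 1)
    if bias is not None:
        out = out + bias.data[None, :, None, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g: np.ndarray) -> None:
        if weight.requires_grad:
            # (C_out, C_in, kz, ky, kx)
            gw = np.tensordot(g, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, (kz, ky, kx), axis=(2, 3, 4))
            wflip = weight.data[:, :, ::-1, ::-1, ::-1]
            gx = np.tensordot(gwin, wflip, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
            x._accumulate(np.moveaxis(gx, -1, 1))

    return Tensor(out, _parents=parents, _backward=bw)


def avg_pool3d(x: Tensor) -> Tensor:
    """2x average pooling over the three trailing spatial axes."""
    n, c, z, y, w = x.shape
    if z % 2 or y % 2 or w % 2:
        raise ValueError(f"avg_pool3d requires even spatial dims, got {(z, y, w)}")
    r = x.data.reshape(n, c, z // 2, 2, y // 2, 2, w // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def bw(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        x._accumulate(gx)

    return Tensor(out, _parents=(x,), _backward=bw)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling over the trailing spatial axes."""
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)

    def bw(g: np.ndarray) -> None:
        n, c, z, y, w = g.shape
        gx = g.reshape(n, c, z // 2, 2, y // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))
        x._accumulate(gx)

    return Tensor(out, _parents=(x,), _backward=bw)


def parameters_of(params: Iterable[Tensor]) -> list[Tensor]:
    return [p for p in params if p.requires_grad]
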