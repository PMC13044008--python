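"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operator set the gated sentiment encoder and
its composite objective need: broadcasting arithmetic, batched matmul,
sigmoid/tanh/relu, numerically stable softmax and log-softmax, reductions,
reshaping, gather, and a gradient-reversal operator for domain-adversarial
training. Gradients are accumulated in float64 by topological-order backward
passes; correctness is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "gradient_reversal", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over dimensions that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum dims of size 1 that were expanded
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (inference paths)."""

    def __enter__(self) -> None:
        self._prev = _GradMode.enabled
        _GradMode.enabled = False

    def __exit__(self, *exc) -> None:
        _GradMode.enabled = self._prev


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GradMode.enabled
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        req = _GradMode.enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req and backward is not None:
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = lambda: backward(out)
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data + other.data

        def bwd(out: Tensor) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return Tensor._make(data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accum(-out.grad)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data * other.data

        def bwd(out: Tensor) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._make(data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data / other.data

        def bwd(out: Tensor) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -out.grad * self.data / (other.data ** 2), other.shape))

        return Tensor._make(data, (self, other), bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        data = self.data ** p

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data @ other.data

        def bwd(out: Tensor) -> None:
            g = out.grad
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1 and other.data.ndim == 1:
                    gb = self.data * g
                elif other.data.ndim == 1:
                    # grad wrt vector b in A @ b: sum_t A[..., t, :] * g[..., t]
                    gb = (self.data * np.expand_dims(g, -1)).reshape(
                        -1, self.data.shape[-1]).sum(axis=0)
                elif self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(data, (self, other), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * data)

        return Tensor._make(data, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(out: Tensor) -> None:
            self._accum(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self) -> "Tensor":
        data = np.sqrt(self.data)

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * 0.5 / data)

        return Tensor._make(data, (self,), bwd)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * (1.0 - data ** 2))

        return Tensor._make(data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        x = self.data
        data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * data * (1.0 - data))

        return Tensor._make(data, (self,), bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def clamp_min(self, lo: float) -> "Tensor":
        mask = self.data >= lo

        def bwd(out: Tensor) -> None:
            self._accum(out.grad * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(out: Tensor) -> None:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape) -> "Tensor":
        data = self.data.reshape(*shape)

        def bwd(out: Tensor) -> None:
            self._accum(out.grad.reshape(self.shape))

        return Tensor._make(data, (self,), bwd)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        data = np.swapaxes(self.data, a, b)

        def bwd(out: Tensor) -> None:
            self._accum(np.swapaxes(out.grad, a, b))

        return Tensor._make(data, (self,), bwd)

    @property
    def T(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def bwd(out: Tensor) -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        return Tensor._make(data, (self,), bwd)

    # ------------------------------------------------------------- composites
    def softmax(self, axis: int = -1) -> "Tensor":
        # max-shift is a constant w.r.t. the graph: softmax is shift-invariant
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    def layer_norm(self, gain: "Tensor", bias: "Tensor",
                   eps: float = 1e-5) -> "Tensor":
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered / (var + eps).sqrt() * gain + bias


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(out: Tensor) -> None:
        grads = np.split(out.grad, len(tensors), axis=axis)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t._accum(np.squeeze(g, axis=axis))

    return Tensor._make(data, tensors, bwd)


def gradient_reversal(x: Tensor, scale: float) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-scale``.

    The construct that lets a domain discriminator's loss push the encoder
    toward domain-confusing features: minimizing downstream of this node
    maximizes upstream.
    """

    def bwd(out: Tensor) -> None:
        x._accum(-scale * out.grad)

    return Tensor._make(x.data.copy(), (x,), bwd)
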