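"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the FCN+NLSTM classifier: a tape-based
``Tensor`` with the handful of differentiable operations the architecture
needs (broadcasted arithmetic, matmul, 1-D convolution, the usual
activations, slicing/concat/reshape, mean, and a fused softmax
cross-entropy), plus Glorot initialisation and an Adam optimiser.  All
computation is float64 and single-threaded NumPy, so results are
bit-reproducible for a fixed seed.  Gradients are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self.grad += _unbroadcast(out.grad, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(out.grad, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                self.grad += out.grad @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ out.grad

        out = self._make(out_data, (self, other), backward)
        return out

    # -- activations -----------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward():
            if self.requires_grad:
                self.grad += out.grad * (self.data > 0)

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            if self.requires_grad:
                self.grad += out.grad * out_data * (1.0 - out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self.grad += out.grad * (1.0 - out_data**2)

        out = self._make(out_data, (self,), backward)
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward():
            if self.requires_grad:
                self.grad += out.grad.reshape(self.data.shape)

        out = self._make(out_data, (self,), backward)
        return out

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward():
            if self.requires_grad:
                np.add.at(self.grad, key, out.grad)

        out = self._make(out_data, (self,), backward)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self.grad += np.broadcast_to(g, self.data.shape)

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t.grad += out.grad[tuple(sl)]

    out = tensors[0]._make(out_data, tuple(tensors), backward)
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Valid 1-D convolution (cross-correlation) along the step axis.

    ``x`` is (batch, steps, channels); ``w`` is (kernel, channels,
    out_channels); ``b`` is (out_channels,).  Output has
    ``(steps − kernel)//stride + 1`` steps.
    """
    B, T, C = x.data.shape
    K, Cin, Cout = w.data.shape
    if Cin != C:
        raise ValueError(
            f"input has {C} channels but kernel expects {Cin} "
            f"(input {x.data.shape}, kernel {w.data.shape})"
        )
    if K > T:
        raise ValueError(f"kernel length {K} exceeds {T} input steps")
    Tp = (T - K) // stride + 1
    idx = np.arange(Tp)[:, None] * stride + np.arange(K)[None, :]  # (Tp, K)
    cols = x.data[:, idx, :]  # (B, Tp, K, C)
    flat = cols.reshape(B * Tp, K * C)
    out_data = (flat @ w.data.reshape(K * C, Cout) + b.data).reshape(B, Tp, Cout)

    def backward():
        g = out.grad.reshape(B * Tp, Cout)
        if w.requires_grad:
            w.grad += (flat.T @ g).reshape(K, C, Cout)
        if b.requires_grad:
            b.grad += g.sum(axis=0)
        if x.requires_grad:
            dcols = (g @ w.data.reshape(K * C, Cout).T).reshape(B, Tp, K, C)
            dx = np.zeros_like(x.data)
            np.add.at(dx, (slice(None), idx), dcols)
            x.grad += dx

    out = x._make(out_data, (x, w, b), backward)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-NumPy softmax (used at prediction time)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of (batch, classes) logits vs int labels."""
    labels = np.asarray(labels, dtype=int)
    B = logits.data.shape[0]
    p = softmax(logits.data)
    eps = 1e-300
    loss = -np.mean(np.log(p[np.arange(B), labels] + eps))

    def backward():
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(B), labels] -= 1.0
            logits.grad += out.grad * g / B

    out = logits._make(np.asarray(loss), (logits,), backward)
    return out


# -- parameters and optimisation ----------------------------------------


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def parameter(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    return Tensor(glorot(rng, shape), requires_grad=True)


def zeros_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
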