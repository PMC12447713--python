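"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order and accumulates gradients.  The op set is exactly what the
forecasting models in this package need (broadcast arithmetic, matmul,
pointwise nonlinearities, softmax, reductions, reshaping, indexed gathers);
it is not a general tensor library.  All gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (for evaluation loops)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    if grad.shape == shape:
        return grad
    # sum away leading dims added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum dims that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A float64 array plus the tape machinery to differentiate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        # First contribution may alias the producer's buffer; it is only
        # mutated in place once this tensor owns a private copy.
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _make(np.add(self.data, other.data), (self, other))
        if out._parents:
            def _bw():
                if self.requires_grad or self._parents:
                    self._accum(_unbroadcast(out.grad, self.shape))
                if other.requires_grad or other._parents:
                    other._accum(_unbroadcast(out.grad, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(np.multiply(self.data, other.data), (self, other))
        if out._parents:
            def _bw():
                if self.requires_grad or self._parents:
                    self._accum(_unbroadcast(out.grad * other.data, self.shape))
                if other.requires_grad or other._parents:
                    other._accum(_unbroadcast(out.grad * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _make(np.power(self.data, exponent), (self,))
        if out._parents:
            def _bw():
                self._accum(
                    _unbroadcast(
                        out.grad * exponent * np.power(self.data, exponent - 1.0),
                        self.shape,
                    )
                )
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out._parents:
            def _bw():
                g = out.grad
                if self.requires_grad or self._parents:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad or other._parents:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = _bw
        return out

    # -- pointwise ----------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = _make(np.where(mask, self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * (1.0 - y * y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * y)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def sin(self):
        out = _make(np.sin(self.data), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * np.cos(self.data))
        return out

    def cos(self):
        out = _make(np.cos(self.data), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * -np.sin(self.data))
        return out

    def gelu(self):
        """Gaussian-error linear unit (tanh approximation)."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = _make(0.5 * x * (1.0 + t), (self,))
        if out._parents:
            def _bw():
                dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
                dgelu = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
                self._accum(out.grad * dgelu)
            out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = _make(y, (self,))
        if out._parents:
            def _bw():
                g = out.grad
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))
            out._backward = _bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def _bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation -------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            fancy = any(
                isinstance(i, (np.ndarray, list)) for i in
                (idx if isinstance(idx, tuple) else (idx,))
            )
            def _bw():
                g = np.zeros_like(self.data)
                if fancy:
                    np.add.at(g, idx, out.grad)  # repeated indices accumulate
                else:
                    g[idx] = out.grad
                self._accum(g)
            out._backward = _bw
        return out

    def take(self, indices: np.ndarray, axis: int = 0):
        """Gather rows; the adjoint scatter-adds (used for embedding lookup)."""
        indices = np.asarray(indices)
        out = _make(np.take(self.data, indices, axis=axis), (self,))
        if out._parents:
            def _bw():
                g = np.zeros_like(self.data)
                if axis == 0:
                    np.add.at(g, indices, out.grad)
                else:  # pragma: no cover - only axis 0 used in the models
                    raise NotImplementedError
                self._accum(g)
            out._backward = _bw
        return out


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        tracked = tuple(
            p for p in parents if p.requires_grad or p._parents
        )
        if tracked:
            out._parents = tracked
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _bw():
            grads = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, grads):
                if t.requires_grad or t._parents:
                    t._accum(g)
        out._backward = _bw
    return out


class Parameter(Tensor):
    """A trainable tensor (requires_grad=True by default)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class AdamW:
    """Adam with decoupled weight decay and optional global-norm clipping.

    Defaults follow the forecasting setup used throughout the package:
    lr 3e-4, weight decay 1e-4, betas (0.9, 0.999).
    """

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
        clip_norm: float | None = 1.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bias1
            vhat = v / bias2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
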