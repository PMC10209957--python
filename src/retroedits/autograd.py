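"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph encoder and edit decoder need:
dense linear algebra, pointwise nonlinearities, row gather/scatter for
message passing on graphs, and a numerically stable log-softmax.  Arrays
are float64 throughout, which keeps finite-difference gradient checks
tight.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(
        self,
        data,
        prev: Sequence["Tensor"] = (),
        requires_grad: bool = True,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self._backward: Optional[Callable[[], None]] = None
        self._prev = tuple(prev)
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    # -- graph traversal ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data + other.data, (self, other))

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = _bwd
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other, requires_grad=False) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data * other.data, (self, other))

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data @ other.data, (self, other))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = _bwd
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, out.grad))

        out._backward = _bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = _bwd
        return out


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def _bwd():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))

    out._backward = _bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, (x,))

    def _bwd():
        if x.requires_grad:
            x._accumulate(out.grad * s * (1 - s))

    out._backward = _bwd
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, (x,))

    def _bwd():
        if x.requires_grad:
            x._accumulate(out.grad * (1 - t * t))

    out._backward = _bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = _bwd
    return out


def rows(x: Tensor, idx) -> Tensor:
    """Gather rows ``x[idx]`` (idx may repeat)."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], (x,))

    def _bwd():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, idx, out.grad)
            x._accumulate(g)

    out._backward = _bwd
    return out


def segment_sum(x: Tensor, idx, n_segments: int) -> Tensor:
    """Scatter-add rows of ``x`` into ``n_segments`` buckets by ``idx``."""
    idx = np.asarray(idx, dtype=np.int64)
    data = np.zeros((n_segments, x.data.shape[1]), dtype=np.float64)
    np.add.at(data, idx, x.data)
    out = Tensor(data, (x,))

    def _bwd():
        if x.requires_grad:
            x._accumulate(out.grad[idx])

    out._backward = _bwd
    return out


def dropout(x: Tensor, rate: float, rng: Optional[np.random.Generator]) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (inference)."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * constant(mask)


def log_softmax(x: Tensor) -> Tensor:
    """Stable log-softmax over a 1-D tensor."""
    m = x.data.max()
    z = x.data - m
    lse = m + np.log(np.exp(z).sum())
    out = Tensor(x.data - lse, (x,))

    def _bwd():
        if x.requires_grad:
            softmax = np.exp(out.data)
            x._accumulate(out.grad - softmax * out.grad.sum())

    out._backward = _bwd
    return out


# --------------------------------------------------------------------------
# Parameters and optimization
# --------------------------------------------------------------------------


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam optimizer with global gradient-norm clipping."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: Optional[float] = 10.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        grads = {
            k: (p.grad if p.grad is not None else np.zeros_like(p.data))
            for k, p in self.params.items()
        }
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
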