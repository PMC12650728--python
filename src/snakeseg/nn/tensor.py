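"""A small reverse-mode automatic-differentiation core on numpy arrays.

The segmentation network in this package is built on :class:`Tensor`, a
thin wrapper around ``numpy.ndarray`` that records the operations applied
to it and can back-propagate gradients through them.  Only the operations
the network actually needs are implemented; all heavy convolution kernels
live in :mod:`snakeseg.nn.functional` as dedicated primitives that lower
to BLAS matrix products.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "as_tensor", "concatenate", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode).

    Inside the context no operation records parents or backward closures,
    so intermediates are freed as soon as they go out of scope.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An N-d array with reverse-mode autodiff.

    Parameters
    ----------
    data:
        Array-like payload; floats are kept in their given dtype
        (float32 throughout the network, float64 in gradient checks).
    requires_grad:
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32 if not isinstance(data, np.ndarray) else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        if _GRAD_ENABLED:
            self._parents = _parents
            self._backward = _backward
        else:
            self._parents = ()
            self._backward = None

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _needs_graph(*tensors: "Tensor") -> bool:
        return any(t.requires_grad or t._parents for t in tensors)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (default seed: ones).

        One-shot: the recorded graph is dismantled afterwards so closures
        (which participate in reference cycles) free their buffers
        immediately instead of waiting for the garbage collector.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate graph state eagerly
            if node is not self and not node.requires_grad and node._parents:
                node.grad = None
            node._backward = None
            node._parents = ()

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other, dtype=self.dtype)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw if Tensor._needs_graph(self, other) else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))

        def _bw(g):
            self._accumulate(-g)

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def __sub__(self, other) -> "Tensor":
        other = as_tensor(other, dtype=self.dtype)
        out = Tensor(self.data - other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(-g, other.data.shape))

        out._backward = _bw if Tensor._needs_graph(self, other) else None
        return out

    def __rsub__(self, other) -> "Tensor":
        other = as_tensor(other, dtype=self.dtype)
        return other.__sub__(self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other, dtype=self.dtype)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw if Tensor._needs_graph(self, other) else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other, dtype=self.dtype)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = _bw if Tensor._needs_graph(self, other) else None
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other, dtype=self.dtype) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, _parents=(self,))

        def _bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))

        def _bw(g):
            self._accumulate(g * out.data)

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def _bw(g):
            self._accumulate(g / self.data)

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), _parents=(self,))

        def _bw(g):
            self._accumulate(g * 0.5 / out.data)

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _parents=(self,))

        def _bw(g):
            self._accumulate(g * (1.0 - out.data**2))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def sigmoid(self) -> "Tensor":
        # numerically safe logistic: clip the exponent, not the output
        d = self.data
        val = 1.0 / (1.0 + np.exp(-np.clip(d, -60, 60)))
        out = Tensor(val.astype(d.dtype), _parents=(self,))

        def _bw(g):
            self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def erf(self) -> "Tensor":
        out = Tensor(_special.erf(self.data).astype(self.dtype), _parents=(self,))

        def _bw(g):
            self._accumulate(g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data**2))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def clip(self, lo: float | None, hi: float | None) -> "Tensor":
        """Clamp values; gradient is passed through only inside the range."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi

        def _bw(g):
            self._accumulate(g * inside)

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, _parents=(self,))
        mask = self.data == m
        counts = mask.sum(axis=axis, keepdims=True)

        def _bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * (g / counts))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def _bw(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def _bw(g):
            self._accumulate(g.transpose(inv))

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _parents=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _bw if Tensor._needs_graph(self) else None
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other, dtype=self.dtype)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = _bw if Tensor._needs_graph(self, other) else None
        return out

    __matmul__ = matmul


def as_tensor(x, dtype=None) -> Tensor:
    """Wrap array-like data; float64 is preserved, everything else becomes
    float32 (the network's working precision)."""
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x) if dtype is None else np.asarray(x, dtype=dtype))


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw if Tensor._needs_graph(*tensors) else None
    return out
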