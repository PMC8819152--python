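"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float array and records the operations applied to
it; ``Tensor.backward()`` walks the recorded graph in reverse topological
order accumulating gradients.  The op set is exactly what the detector
needs: broadcasting arithmetic, matmul, dilated/strided 2-D convolution
(im2col-free, via strided window views), nearest-neighbour upsampling,
reductions, gather/crop, sigmoid/relu, and numerically stable composite
losses (softmax cross-entropy, binary cross-entropy with logits, smooth-L1).

All gradients are verified against central finite differences in the test
suite.  float64 throughout: problem sizes here are tiny and exactness is
worth more than speed.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


class _NoGrad:
    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True

    def __exit__(self, *exc):
        _NoGrad._active = self._prev


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and not _NoGrad._active
        self._backward = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad=True) -> "Tensor":
        if _NoGrad._active or not requires_grad:
            return Tensor(data)
        out = Tensor(data, requires_grad=True)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor) and p.requires_grad)
        out._backward = backward
        return out

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
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
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward, self.requires_grad)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1 - s))

        return Tensor._make(s, (self,), backward, self.requires_grad)

    def exp(self) -> "Tensor":
        e = np.exp(np.clip(self.data, -60, 60))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        return Tensor._make(e, (self,), backward, self.requires_grad)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis=axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis=axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, argmax, gg, axis=axis)
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward, self.requires_grad)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward, self.requires_grad)

    def take(self, indices: np.ndarray, axis: int = 0) -> "Tensor":
        indices = np.asarray(indices, dtype=np.intp)
        out_data = np.take(self.data, indices, axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            sl = [slice(None)] * self.ndim
            for k, idx in enumerate(indices):
                sl[axis] = idx
                gsl = [slice(None)] * self.ndim
                gsl[axis] = k
                grad[tuple(sl)] += g[tuple(gsl)]
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def crop2d(self, y0: int, y1: int, x0: int, x1: int) -> "Tensor":
        """Spatial slice of an NCHW tensor, differentiable (scatter-add back)."""
        out_data = self.data[:, :, y0:y1, x0:x1]

        def backward(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            grad[:, :, y0:y1, x0:x1] = g
            self._accumulate(grad)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- conv / resampling ----------------------------------------------------
    def conv2d(
        self,
        weight: "Tensor",
        bias: Optional["Tensor"] = None,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
    ) -> "Tensor":
        """2-D convolution (cross-correlation) on NCHW input.

        Output spatial size follows the standard formula; ``padding=dilation``
        with a 3x3 kernel preserves spatial dims at stride 1 for any dilation.
        """
        x, w = self, weight
        N, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
        Hk = dilation * (kh - 1) + 1
        Wk = dilation * (kw - 1) + 1
        Ho = (H + 2 * padding - Hk) // stride + 1
        Wo = (W + 2 * padding - Wk) // stride + 1
        if Ho < 1 or Wo < 1:
            raise ValueError("conv2d: output would be empty")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (Hk, Wk), axis=(2, 3))
        win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # N,C,Ho,Wo,kh,kw
        out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)

        def backward(g):
            if w.requires_grad:
                w._accumulate(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[
                            :,
                            :,
                            i * dilation : i * dilation + stride * Ho : stride,
                            j * dilation : j * dilation + stride * Wo : stride,
                        ] += dcols[:, :, :, :, i, j]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(dxp)

        parents = (x, w) if bias is None else (x, w, bias)
        req = x.requires_grad or w.requires_grad or (bias is not None and bias.requires_grad)
        return Tensor._make(out_data, parents, backward, req)

    def upsample_nearest(self, scale: int = 2) -> "Tensor":
        """Nearest-neighbour upsampling of an NCHW tensor by an integer factor."""
        out_data = self.data.repeat(scale, axis=2).repeat(scale, axis=3)

        def backward(g):
            if not self.requires_grad:
                return
            N, C, H, W = self.shape
            gr = g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5))
            self._accumulate(gr)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- composite losses ------------------------------------------------------
    def softmax_cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Per-row cross-entropy of (N, K) logits against integer labels (N,)."""
        labels = np.asarray(labels, dtype=np.intp)
        z = self.data - self.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        n = self.shape[0]
        losses = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))

        def backward(g):
            if not self.requires_grad:
                return
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            self._accumulate(grad * np.asarray(g).reshape(-1, 1))

        return Tensor._make(losses, (self,), backward, self.requires_grad)

    def bce_with_logits(self, targets: np.ndarray) -> "Tensor":
        """Elementwise binary cross-entropy on logits (numerically stable)."""
        t = np.asarray(targets, dtype=np.float64)
        x = self.data
        losses = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

        def backward(g):
            if not self.requires_grad:
                return
            s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
            self._accumulate(g * (s - t))

        return Tensor._make(losses, (self,), backward, self.requires_grad)

    def smooth_l1(self, targets: np.ndarray, beta: float = 1.0) -> "Tensor":
        """Elementwise Huber/smooth-L1 against constant targets."""
        d = self.data - np.asarray(targets, dtype=np.float64)
        absd = np.abs(d)
        losses = np.where(absd < beta, 0.5 * d * d / beta, absd - 0.5 * beta)

        def backward(g):
            if not self.requires_grad:
                return
            self._accumulate(g * np.where(absd < beta, d / beta, np.sign(d)))

        return Tensor._make(losses, (self,), backward, self.requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    return Tensor._make(out_data, tuple(tensors), backward, req)
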