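"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the tensor core the package's neural models (the trend LSTM and the
residual Informer-style network) are built on.  It supports exactly the set of
differentiable operations those models need — broadcast arithmetic, batched
matrix products, the sigmoid/tanh/ReLU nonlinearities, numerically stable
softmax, reductions, slicing/concatenation, cumulative sums, 1-D convolution
and max-pooling — plus an Adam optimizer.  Gradient correctness is checked
against central finite differences in the test suite.

Design notes
------------
* A :class:`Tensor` wraps a float64 ``numpy.ndarray`` and records a backward
  closure; :meth:`Tensor.backward` runs a topological sweep.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
* Everything is CPU/numpy — model sizes here (d_model ≈ 32–512, sequence
  lengths ≈ 24–168) do not need more.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with reverse-mode gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from long sequences overflow recursion
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
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._make(e, (self,), backward)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / r)

        return self._make(r, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis: int) -> "Tensor":
        out_data = np.cumsum(self.data, axis=axis)

        def backward(g):
            if self.requires_grad:
                rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
                self._accum(rev)

        return self._make(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- structured ops -------------------------------------------------------
    def pad_last2(self, pad_len: int, value: float = 0.0, axis: int = -2) -> "Tensor":
        """Pad ``pad_len`` rows of ``value`` on both ends of ``axis``."""
        width = [(0, 0)] * self.data.ndim
        width[axis % self.data.ndim] = (pad_len, pad_len)
        out_data = np.pad(self.data, width, constant_values=value)
        sl = [slice(None)] * self.data.ndim
        sl[axis % self.data.ndim] = slice(pad_len, pad_len + self.data.shape[axis])
        sl = tuple(sl)

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        return self._make(out_data, (self,), backward)

    def conv1d_same(self, weight: "Tensor", bias: "Tensor" | None = None) -> "Tensor":
        """1-D convolution over axis -2 with 'same' zero padding.

        self: [..., L, C_in]; weight: [K, C_in, C_out] with odd K.
        """
        K = weight.shape[0]
        half = K // 2
        L = self.data.shape[-2]
        xp = self.pad_last2(half)  # [..., L+2h, C_in]
        # im2col: stack K shifted views and contract
        cols = concatenate([xp[..., k : k + L, :] for k in range(K)], axis=-1)
        # cols: [..., L, K*C_in]; weight reshaped [K*C_in, C_out]
        w2 = weight.reshape(K * weight.shape[1], weight.shape[2])
        out = cols @ w2
        if bias is not None:
            out = out + bias
        return out

    def maxpool1d_half(self) -> "Tensor":
        """Max-pool over axis -2, kernel 3, stride 2, padding 1 → ceil(L/2) rows."""
        L = self.data.shape[-2]
        if L < 2:
            raise ValueError("maxpool1d_half requires sequence length >= 2")
        xp = self.pad_last2(1, value=-np.inf)
        starts = np.arange(0, L + 2 - 2, 2)  # ceil(L/2) windows
        windows = np.stack(
            [xp.data[..., s : s + 3, :] for s in starts], axis=-3
        )  # [..., P, 3, C]
        out_data = windows.max(axis=-2)
        argmax = windows.argmax(axis=-2)  # [..., P, C] in 0..2

        def backward(g):
            if self.requires_grad:
                full = np.zeros(xp.data.shape, dtype=np.float64)
                # scatter grads back through the argmax positions
                P = len(starts)
                lead = full.shape[:-2]
                C = full.shape[-1]
                idx_rows = argmax + starts.reshape(
                    (1,) * len(lead) + (P, 1)
                )  # absolute padded row index
                flat = full.reshape(-1, full.shape[-2], C)
                gr = g.reshape(-1, P, C)
                ir = idx_rows.reshape(-1, P, C)
                b_idx = np.arange(flat.shape[0])[:, None, None]
                c_idx = np.arange(C)[None, None, :]
                np.add.at(flat, (b_idx, ir, c_idx), gr)
                full = flat.reshape(full.shape)
                # strip padding rows
                self._accum(full[..., 1 : 1 + L, :])

        return self._make(out_data, (self, ), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis % g.ndim] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Parameter:
    """Standard uniform fan-in initialization: U(−1/√fan_in, 1/√fan_in)."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Parameter(rng.uniform(-bound, bound, size=shape))


class Adam:
    """Adam optimizer with an optional per-epoch multiplicative LR schedule."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
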