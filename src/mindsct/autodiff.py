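"""Minimal reverse-mode automatic differentiation over numpy arrays.

The translation networks and their composite objectives need gradients of
scalar losses with respect to convolutional parameters, including gradients
that flow *through* the neighbourhood-descriptor computation.  This module
provides the small tensor/backprop engine those components are built on:
a :class:`Tensor` wrapping a numpy array, a handful of differentiable
operations (elementwise math, reductions, slicing, padding, clamped spatial
shifts, im2col-based 2-D convolution, nearest-neighbour upsampling) and an
Adam optimiser.

Design notes
------------
* Graphs are built eagerly; ``Tensor.backward()`` runs a topological sweep.
* Operations skip graph construction entirely when no input requires
  gradients, so inference costs plain numpy.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
* Default parameter dtype is float32; the engine preserves input dtypes so
  float64 graphs can be used for numerical gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Adam",
    "stack",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ utils
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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative post-order to avoid recursion limits on deep graphs
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    visiting.append((child, False))
        del stack_
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # --------------------------------------------------------- binary helpers
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(prev) if req else ())
        if req:
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1))

        return self._make(a.data ** p, (a,), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        scale = np.where(mask, 1.0, slope)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * scale)

        return self._make(a.data * scale, (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * sign)

        return self._make(np.abs(a.data), (a,), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        """Clip values; gradient is zero outside [lo, hi]."""
        a = self
        out_data = np.clip(a.data, lo, hi)
        interior = np.ones_like(a.data, dtype=bool)
        if lo is not None:
            interior &= a.data > lo
        if hi is not None:
            interior &= a.data < hi

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * interior)

        return self._make(out_data, (a,), backward)

    def maximum(self, other):
        other = self._coerce(other)
        a, b = self, other
        take_a = a.data >= b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * take_a, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * ~take_a, b.shape))

        return self._make(np.maximum(a.data, b.data), (a, b), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along an axis; ties share the gradient equally."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not a.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(mask * (gg / counts))

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return self._make(data, (a,), backward)

    # ------------------------------------------------------- shape operations
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return self._make(a.data[idx], (a,), backward)

    # ---------------------------------------------------- spatial operations
    def pad2d(self, pad: int, mode: str = "replicate"):
        """Pad the trailing two axes by ``pad`` on each side."""
        a = self
        if pad == 0:
            return a * 1.0
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
        np_mode = {"replicate": "edge", "zero": "constant", "reflect": "reflect"}[mode]
        out_data = np.pad(a.data, width, mode=np_mode)
        H, W = a.shape[-2:]

        def backward(g):
            if not a.requires_grad:
                return
            if mode == "zero":
                a._accumulate(g[..., pad:pad + H, pad:pad + W])
                return
            if mode == "reflect":
                rows = np.abs(np.arange(-pad, H + pad))
                rows = np.where(rows >= H, 2 * (H - 1) - rows, rows)
                cols = np.abs(np.arange(-pad, W + pad))
                cols = np.where(cols >= W, 2 * (W - 1) - cols, cols)
                full = np.zeros_like(a.data)
                flat = full.reshape(-1, H, W)
                gflat = g.reshape(-1, H + 2 * pad, W + 2 * pad)
                b = np.arange(flat.shape[0])[:, None, None]
                np.add.at(flat, (b, rows[None, :, None], cols[None, None, :]),
                          gflat)
                a._accumulate(full)
                return
            # replicate: border gradients fold onto the edge rows/columns
            tmp = g[..., pad:pad + H, :].copy()
            tmp[..., 0, :] += g[..., :pad, :].sum(axis=-2)
            tmp[..., H - 1, :] += g[..., pad + H:, :].sum(axis=-2)
            out = tmp[..., :, pad:pad + W].copy()
            out[..., :, 0] += tmp[..., :, :pad].sum(axis=-1)
            out[..., :, W - 1] += tmp[..., :, pad + W:].sum(axis=-1)
            a._accumulate(out)

        return self._make(out_data, (a,), backward)

    def shift2d(self, dy: int, dx: int):
        """Sample ``x[..., i+dy, j+dx]`` with edge-clamped indices."""
        a = self
        H, W = a.shape[-2:]
        rows = np.clip(np.arange(H) + dy, 0, H - 1)
        cols = np.clip(np.arange(W) + dx, 0, W - 1)
        out_data = a.data[..., rows[:, None], cols[None, :]]

        def adjoint_axis(g, d, size, axis):
            """Adjoint of a clamped shift along one axis (slice + edge sum)."""
            if d == 0:
                return g
            out = np.zeros_like(g)
            sl = [slice(None)] * g.ndim
            if d > 0:
                d_ = min(d, size - 1)
                src, dst = list(sl), list(sl)
                src[axis] = slice(0, size - d_)
                dst[axis] = slice(d_, size)
                out[tuple(dst)] += g[tuple(src)]
                edge, last = list(sl), list(sl)
                edge[axis] = slice(size - d_, size)
                last[axis] = size - 1
                out[tuple(last)] += g[tuple(edge)].sum(axis=axis)
            else:
                d_ = min(-d, size - 1)
                src, dst = list(sl), list(sl)
                src[axis] = slice(d_, size)
                dst[axis] = slice(0, size - d_)
                out[tuple(dst)] += g[tuple(src)]
                edge, first = list(sl), list(sl)
                edge[axis] = slice(0, d_)
                first[axis] = 0
                out[tuple(first)] += g[tuple(edge)].sum(axis=axis)
            return out

        def backward(g):
            if not a.requires_grad:
                return
            gg = adjoint_axis(np.asarray(g), dy, H, g.ndim - 2)
            gg = adjoint_axis(gg, dx, W, g.ndim - 1)
            a._accumulate(gg)

        return self._make(out_data, (a,), backward)

    def upsample_nearest(self, scale: int):
        a = self
        out_data = a.data.repeat(scale, axis=-2).repeat(scale, axis=-1)
        H, W = a.shape[-2:]

        def backward(g):
            if not a.requires_grad:
                return
            lead = g.shape[:-2]
            gg = g.reshape(lead + (H, scale, W, scale)).sum(axis=(-3, -1))
            a._accumulate(gg)

        return self._make(out_data, (a,), backward)

    # --------------------------------------------------------- linear algebra
    def matmul(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    def conv2d(self, weight: "Tensor", stride: int = 1):
        """2-D cross-correlation, NCHW input × OIHW weight, no padding."""
        a, w = self, self._coerce(weight)
        N, C, H, W = a.shape
        O, C2, kh, kw = w.shape
        if C != C2:
            raise ValueError(f"channel mismatch: input {C} vs weight {C2}")
        oh = (H - kh) // stride + 1
        ow = (W - kw) // stride + 1
        s = a.data.strides
        cols = np.lib.stride_tricks.as_strided(
            a.data,
            shape=(N, C, kh, kw, oh, ow),
            strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        ).reshape(N, C * kh * kw, oh * ow)
        wmat = w.data.reshape(O, C * kh * kw)
        out_data = (wmat @ cols).reshape(N, O, oh, ow)

        def backward(g):
            gmat = g.reshape(N, O, oh * ow)
            if w.requires_grad:
                gw = (gmat.transpose(1, 0, 2).reshape(O, -1)
                      @ cols.transpose(0, 2, 1).reshape(-1, C * kh * kw))
                w._accumulate(gw.reshape(w.shape))
            if a.requires_grad:
                dcols = wmat.T @ gmat
                dcols = dcols.reshape(N, C, kh, kw, oh, ow)
                dx = np.zeros_like(a.data)
                for i in range(kh):
                    for j in range(kw):
                        dx[:, :, i:i + oh * stride:stride,
                           j:j + ow * stride:stride] += dcols[:, :, i, j]
                a._accumulate(dx)

        return self._make(out_data, (a, w), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        def backward(g):
            pieces = np.split(g, len(tensors), axis=axis)
            for t, p in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(np.squeeze(p, axis=axis))
        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an existing axis."""
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, _prev=tuple(tensors) if req else ())
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            pieces = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(p)
        out._backward = backward
    return out


class Parameter(Tensor):
    """A leaf tensor that an optimiser updates."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class providing recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)
        elif isinstance(value, dict):
            for v in value.values():
                Module._collect_value(v, params, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = a.astype(p.data.dtype, copy=True)


class Adam:
    """Adam optimiser (decoupled from the modules it updates)."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
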