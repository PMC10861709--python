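"""Minimal reverse-mode automatic differentiation for small 1-D conv nets.

This is a compact NumPy autodiff engine sized for the needs of this package:
dilated 1-D convolutions, batch normalization, max pooling, softmax attention
and binary cross-entropy, trained with Adam.  Tensors hold float64 arrays;
``backward()`` runs reverse topological accumulation.  The engine favors
clarity and correctness over speed — convolutions are expressed as strided
windows contracted with einsum, which is adequate for the desk-scale networks
used here.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "conv1d_same",
    "maxpool1d_same",
    "bce_with_logits",
    "softmax",
    "Module",
    "Conv1d",
    "BatchNorm1d",
    "Linear",
    "Adam",
]


def _as_array(value) -> np.ndarray:
    return np.asarray(value, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents: Tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(gy):
            if self.requires_grad:
                self._accumulate(_unbroadcast(gy, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(gy, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(gy):
            if self.requires_grad:
                self._accumulate(-gy)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(gy):
            if self.requires_grad:
                self._accumulate(_unbroadcast(gy * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(gy * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(gy):
            if self.requires_grad:
                self._accumulate(_unbroadcast(gy / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-gy * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy * e * self.data ** (e - 1.0))

        return Tensor._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(gy):
            if self.requires_grad:
                ga = gy @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ gy
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def take_rows(self, indices: Sequence[int], axis: int = 0):
        """Gather along ``axis`` (backward scatter-adds)."""
        idx = np.asarray(indices, dtype=int)

        def backward(gy):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, (slice(None),) * axis + (idx,), gy)
                self._accumulate(g)

        return Tensor._make(np.take(self.data, idx, axis=axis), (self,), backward)

    # -- reductions & nonlinearities --------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(gy):
            if not self.requires_grad:
                return
            g = gy
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def relu(self):
        mask = self.data > 0

        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(gy):
            if self.requires_grad:
                self._accumulate(gy * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-subtracted)."""
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(gy):
        if t.requires_grad:
            dot = (gy * out_data).sum(axis=axis, keepdims=True)
            t._accumulate(out_data * (gy - dot))

    return Tensor._make(out_data, (t,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(gy):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = (slice(None),) * axis + (slice(lo, hi),)
                t._accumulate(gy[sl])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors),
        backward,
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)

    def backward(gy):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(gy, i, axis=axis))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv1d_same(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    """Stride-1 dilated conv with zero 'same' padding.

    ``x``: (B, C, T); ``w``: (F, C, K) -> (B, F, T).
    """
    B, C, T = x.shape
    F, Cw, K = w.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    span = (K - 1) * dilation + 1
    left = (span - 1) // 2
    right = span - 1 - left
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, span, axis=2)[
        ..., ::dilation
    ]  # (B, C, T, K)
    out_data = np.einsum("bctk,fck->bft", windows, w.data, optimize=True)

    def backward(gy):
        if w.requires_grad:
            gw = np.einsum("bctk,bft->fck", windows, gy, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k * dilation : k * dilation + T] += np.einsum(
                    "bft,fc->bct", gy, w.data[:, :, k], optimize=True
                )
            x._accumulate(gxp[:, :, left : left + T])

    return Tensor._make(out_data, (x, w), backward)


def maxpool1d_same(x: Tensor, kernel: int = 3) -> Tensor:
    """Stride-1 max pooling with 'same' extent, (B, C, T) -> (B, C, T)."""
    B, C, T = x.shape
    left = (kernel - 1) // 2
    right = kernel - 1 - left
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right)), constant_values=-np.inf)
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    arg = windows.argmax(axis=-1)  # (B, C, T)
    out_data = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]

    def backward(gy):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            b_idx, c_idx, t_idx = np.meshgrid(
                np.arange(B), np.arange(C), np.arange(T), indexing="ij"
            )
            np.add.at(gxp, (b_idx, c_idx, t_idx + arg), gy)
            x._accumulate(gxp[:, :, left : left + T])

    return Tensor._make(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable form)."""
    z = logits.data
    y = _as_array(targets)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(gy):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(gy * (sig - y) / n)

    return Tensor._make(loss.mean(), (logits,), backward)


# ---------------------------------------------------------------------------
# layers


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def set_training(self, mode: bool) -> None:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(mode)
        if hasattr(self, "training"):
            self.training = mode

    def state_arrays(self, prefix: str = "") -> dict:
        """Flat name -> ndarray map of parameters and buffers (for saving)."""
        out = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value.data
            elif isinstance(value, np.ndarray):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.state_arrays(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)) and any(
                isinstance(v, Module) for v in value
            ):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
        return out

    def load_state_arrays(self, arrays: dict, prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and key in arrays:
                value.data = _as_array(arrays[key]).reshape(value.data.shape)
            elif isinstance(value, np.ndarray) and key in arrays:
                setattr(self, name, _as_array(arrays[key]).reshape(value.shape))
            elif isinstance(value, Module):
                value.load_state_arrays(arrays, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, prefix=f"{key}.{i}.")


class Conv1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)),
            requires_grad=True,
        )
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.weight, dilation=self.dilation)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat_data = (x.data - mu[None, :, None]) / std[None, :, None]
        gamma, beta = self.gamma, self.beta

        def backward(gy):
            if gamma.requires_grad:
                gamma._accumulate((gy * xhat_data).sum(axis=(0, 2)))
            if beta.requires_grad:
                beta._accumulate(gy.sum(axis=(0, 2)))
            if x.requires_grad:
                dxhat = gy * gamma.data[None, :, None]
                if self.training:
                    B, C, T = x.shape
                    n = B * T
                    s1 = dxhat.sum(axis=(0, 2), keepdims=True)
                    s2 = (dxhat * xhat_data).sum(axis=(0, 2), keepdims=True)
                    gx = (dxhat - s1 / n - xhat_data * s2 / n) / std[None, :, None]
                else:
                    gx = dxhat / std[None, :, None]
                x._accumulate(gx)

        out_data = (
            gamma.data[None, :, None] * xhat_data + beta.data[None, :, None]
        )
        return Tensor._make(out_data, (x, gamma, beta), backward)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
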