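"""Minimal reverse-mode autograd over NumPy arrays for the segmentation net.

Implements exactly the operations the nested-U architecture needs — 2D
convolution (stride 1, same padding, optional dilation), batch
normalization, ReLU, sigmoid, 2x2 max pooling, nearest-neighbour upsampling
by integer factors, channel concatenation, elementwise add, and a
numerically stable binary cross-entropy on logits.  Tensors record their
parents and a backward closure; ``Tensor.backward`` runs a topological
sweep.  Everything is float32 and fully deterministic: no threading, no
in-place aliasing, fixed reduction order.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Conv2d",
    "BatchNorm2d",
    "Adam",
    "relu",
    "sigmoid",
    "maxpool2x2",
    "upsample_nearest",
    "concat_channels",
    "bce_with_logits_mean",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor(out_data, parents=(self, other), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=bwd)


def stable_sigmoid(z: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = stable_sigmoid(x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = xr.max(axis=(3, 5))

    def bwd(g):
        if not x.requires_grad:
            return
        expand = out_data[:, :, :, None, :, None]
        mask = (xr == expand).astype(np.float32)
        mask /= np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1.0)
        gx = (mask * g[:, :, :, None, :, None]).reshape(n, c, h, w)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    if factor == 1:
        return x
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def bwd(g):
        if not x.requires_grad:
            return
        n, c, h, w = x.data.shape
        gx = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def bwd(g):
        start = 0
        for t, sz in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[:, start : start + sz])
            start += sz

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def bce_with_logits_mean(logits: Tensor, target: np.ndarray) -> Tensor:
    """Per-pixel mean binary cross-entropy, computed stably from logits."""
    z = logits.data
    t = np.asarray(target, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(loss.mean(), dtype=np.float32)

    def bwd(g):
        if logits.requires_grad:
            p = stable_sigmoid(z)
            logits._accumulate((g * (p - t) / z.size).astype(np.float32))

    return Tensor(out_data, parents=(logits,), backward=bwd)


class Conv2d:
    """3x3 (or kxk) convolution, stride 1, zero-padded to "same" size,
    optional dilation.  He-normal weight init from the supplied RNG."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.kernel_size = k
        self.dilation = dilation

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        k, d = self.kernel_size, self.dilation
        pad = d * (k - 1) // 2
        n, c, h, w = x.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        k_eff = d * (k - 1) + 1
        win = sliding_window_view(xp, (k_eff, k_eff), axis=(2, 3))[..., ::d, ::d]
        # win: (n, c, h, w, k, k) -> cols (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        wmat = self.weight.data.reshape(self.weight.data.shape[0], c * k * k)
        out = cols @ wmat.T + self.bias.data
        out_data = out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        f = self.weight.data.shape[0]

        def bwd(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, f)
            if self.weight.requires_grad:
                gw = gmat.T @ cols
                self.weight._accumulate(gw.reshape(self.weight.data.shape))
                self.bias._accumulate(gmat.sum(axis=0))
            if x.requires_grad:
                gcols = gmat @ wmat  # (n*h*w, c*k*k)
                gcols = gcols.reshape(n, h, w, c, k, k)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i * d : i * d + h, j * d : j * d + w] += gcols[
                            :, :, :, :, i, j
                        ].transpose(0, 3, 1, 2)
                gx = gxp[:, :, pad : pad + h, pad : pad + w] if pad else gxp
                x._accumulate(gx)

        return Tensor(out_data, parents=(x, self.weight, self.bias), backward=bwd)


class BatchNorm2d:
    """Per-channel batch normalization with trainable scale/shift and
    running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.training = True

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
        out_data = xhat * self.gamma.data[None, :, None, None] + self.beta.data[
            None, :, None, None
        ]
        training = self.training

        def bwd(g):
            if self.gamma.requires_grad:
                self.gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
                self.beta._accumulate(g.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            dxhat = g * self.gamma.data[None, :, None, None]
            if training:
                n = g.shape[0] * g.shape[2] * g.shape[3]
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv_std[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)
            else:
                gx = dxhat * inv_std[None, :, None, None]
            x._accumulate(gx.astype(np.float32))

        return Tensor(out_data, parents=(x, self.gamma, self.beta), backward=bwd)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999), deterministic update order."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
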