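"""Neural-network layers built on the autograd :class:`~mosqid.nn.tensor.Tensor`.

Layers follow the familiar Module pattern: parameters are Tensors with
``requires_grad=True``, submodules are discovered through attribute
inspection, and ``train()`` / ``eval()`` toggle batch-norm behaviour.
Initialisation is seeded explicitly through a ``numpy.random.Generator`` so
that two models built from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Linear", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "GlobalAvgPool", "Flatten",
]


class Module:
    """Base class: parameter discovery, train/eval mode, call = forward."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{key}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                yield key, v

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Linear(Module):
    """Affine map (n, d_in) -> (n, d_out), He-uniform initialised."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)
        self.d_in, self.d_out = d_in, d_out

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected input width {self.d_in}, got {x.shape[-1]}")
        return x @ self.weight + self.bias


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride,
                                 j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col, NCHW layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, is_projection: bool = False):
        super().__init__()
        fan_in = c_in * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding, self.kernel = stride, padding, kernel
        self.c_in, self.c_out = c_in, c_out
        # projection shortcuts in residual nets are excluded from the
        # parameter-layer census
        self.is_projection = is_projection

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, s, p = self.kernel, self.stride, self.padding
        cols, oh, ow = _im2col(x.data, k, k, s, p)
        n = x.shape[0]
        wmat = w.data.reshape(self.c_out, -1)
        val = np.einsum("fk,nkl->nfl", wmat, cols).reshape(n, self.c_out, oh, ow)
        val += b.data[None, :, None, None]
        out = Tensor(val, x.requires_grad or w.requires_grad or b.requires_grad,
                     (x, w, b))

        def bwd():
            g = out.grad.reshape(n, self.c_out, oh * ow)
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2)))
            if w.requires_grad:
                dw = np.einsum("nfl,nkl->fk", g, cols)
                w._accumulate(dw.reshape(w.data.shape))
            if x.requires_grad:
                dcols = np.einsum("fk,nfl->nkl", wmat, g)
                x._accumulate(_col2im(dcols, x.data.shape, k, k, s, p, oh, ow))

        out._backward = bwd
        return out


class MaxPool2d(Module):
    """Non-overlapping max pooling with square kernel = stride."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool {k}")
        oh, ow = h // k, w // k
        windows = x.data.reshape(n, c, oh, k, ow, k) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
        # first max per window: deterministic tie-break
        am = windows.argmax(axis=-1)
        val = np.take_along_axis(windows, am[..., None], axis=-1)[..., 0]
        out = Tensor(val, x.requires_grad, (x,))

        def bwd():
            if x.requires_grad:
                g = np.zeros((n, c, oh, ow, k * k))
                np.put_along_axis(g, am[..., None], out.grad[..., None], axis=-1)
                x._accumulate(g.reshape(n, c, oh, ow, k, k)
                              .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))

        out._backward = bwd
        return out


class GlobalAvgPool(Module):
    """(n, c, h, w) -> (n, c) spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x.reshape(n, c, -1).mean(axis=2)


class BatchNorm2d(Module):
    """Batch normalisation over (n, h, w) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps, self.channels = momentum, eps, channels

    def forward(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        val = xhat * g.data[None, :, None, None] + b.data[None, :, None, None]
        out = Tensor(val, x.requires_grad or g.requires_grad, (x, g, b))
        training = self.training

        def bwd():
            go = out.grad
            if b.requires_grad:
                b._accumulate(go.sum(axis=(0, 2, 3)))
            if g.requires_grad:
                g._accumulate((go * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = go * g.data[None, :, None, None]
                if training:
                    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                    t1 = gi - gi.mean(axis=(0, 2, 3), keepdims=True)
                    t2 = xhat * (gi * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                    x._accumulate((t1 - t2) * inv[None, :, None, None])
                else:
                    x._accumulate(gi * inv[None, :, None, None])

        out._backward = bwd
        return out
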