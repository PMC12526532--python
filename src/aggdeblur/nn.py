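"""Layers for the deblurring GAN: Ghost modules, squeeze-and-excitation,
gated half-instance normalization, and a small Module/optimizer system.
"""

from __future__ import annotations

import math
from typing import Iterator, Tuple

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "DepthwiseConv2d", "SEBlock",
    "GhostModule", "GHIN", "AGGBlock", "count_parameters", "Adam",
]


class Module:
    """Base class with recursive parameter discovery and (de)serialization."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar weights in ``model``."""
    return int(sum(p.size for p in model.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(_kaiming(rng, (channels, kernel, kernel), kernel * kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, self.bias,
                                  stride=self.stride, padding=self.padding)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SEBlock(Module):
    """Squeeze-and-excitation channel gate: GAP -> bottleneck -> sigmoid scale."""

    def __init__(self, channels: int, reduction: int = 4, *, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.global_avg_pool()
        s = self.fc1(s).relu()
        s = self.fc2(s).sigmoid()
        return x * s


class GhostModule(Module):
    """Ghost convolution: a primary convolution producing intrinsic channels,
    a cheap depthwise convolution producing complementary channels, channel
    concatenation, optional SE recalibration, then cropping to ``out_ch``.

    ``ratio`` is the total-to-intrinsic channel ratio of the Ghost design.
    """

    def __init__(self, in_ch: int, out_ch: int, *, ratio: int = 2,
                 primary_kernel: int = 3, dw_kernel: int = 3, stride: int = 1,
                 use_se: bool = True, se_reduction: int = 4, relu: bool = True,
                 rng: np.random.Generator):
        if out_ch % ratio:
            raise ValueError("out_ch must be divisible by ratio")
        self.out_ch = out_ch
        self.relu = relu
        init_ch = out_ch // ratio
        self.primary = Conv2d(in_ch, init_ch, primary_kernel, stride=stride,
                              padding=primary_kernel // 2, rng=rng)
        self.cheap = DepthwiseConv2d(init_ch, dw_kernel, padding=dw_kernel // 2, rng=rng)
        # cheap path emits (ratio-1) ghost channels per intrinsic channel; with
        # ratio 2 that is one depthwise pass
        self.se = SEBlock(init_ch * ratio, se_reduction, rng=rng) if use_se else None

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.primary(x)
        if self.relu:
            y1 = y1.relu()
        y2 = self.cheap(y1)
        if self.relu:
            y2 = y2.relu()
        out = Tensor.cat([y1, y2], axis=1)
        if self.se is not None:
            out = self.se(out)
        return out.slice_channels(0, self.out_ch)


class GHIN(Module):
    """Gated half-instance normalization.

    The first ``C_i = floor(C/2)`` channels are standardized per sample and
    channel over spatial positions, converted into a modulation factor
    ``S = gamma * alpha * x_norm + beta`` and applied as ``y_i = (1 + S) * x_i``
    to the raw half; the remaining channels pass through untouched.  With the
    initialization alpha=1, gamma=0, beta=0 the whole block is the identity.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        if channels < 2:
            raise ValueError("GHIN requires at least 2 channels")
        self.channels = channels
        self.n_norm = channels // 2
        self.eps = eps
        shape = (1, self.n_norm, 1, 1)
        self.alpha = Tensor(np.ones(shape, np.float32), requires_grad=True)
        self.gamma = Tensor(np.zeros(shape, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(shape, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"GHIN built for {self.channels} channels, got {x.shape[1]}")
        xi = x.slice_channels(0, self.n_norm)
        xr = x.slice_channels(self.n_norm, self.channels)
        mu = xi.mean(axis=(2, 3), keepdims=True)
        centred = xi - mu
        var = (centred * centred).mean(axis=(2, 3), keepdims=True)
        x_norm = centred / (var + self.eps).sqrt()
        s = self.gamma * self.alpha * x_norm + self.beta
        yi = (1.0 + s) * xi
        return Tensor.cat([yi, xr], axis=1)


class AGGBlock(Module):
    """Attention-Ghost + GHIN fusion refiner used in the top-down pathway."""

    def __init__(self, in_ch: int, out_ch: int, *, primary_kernel: int = 3,
                 se_reduction: int = 4, rng: np.random.Generator):
        self.ghost = GhostModule(in_ch, out_ch, primary_kernel=primary_kernel,
                                 use_se=True, se_reduction=se_reduction, rng=rng)
        self.ghin = GHIN(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.ghin(self.ghost(x))


class Adam:
    """Adaptive-moment optimizer with the standard default moments."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
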