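"""Layer/module abstractions over the autodiff tensors.

Initialisation draws from a caller-supplied ``numpy.random.Generator`` so that
a single seed determines every weight in a model: truncated normal (±2 sd) for
projections and convolutions, unit scale / zero shift for normalisation layers.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "DepthwiseConv2d",
    "Conv1dChannel", "BatchNorm2d", "LayerNorm", "Sequential", "trunc_normal",
]

DTYPE = np.float32


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to ±2 standard deviations (resampling)."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > 2.0
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > 2.0
    return out * std


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                self._assign_buffer(name[len("buffer:"):], value)
            else:
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r}")
                if params[name].shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = value.astype(DTYPE).copy()

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            mod = mod._modules[p]
        mod.register_buffer(parts[-1], value.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = list(mods)

    def forward(self, x):
        for m in self._order:
            x = m(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(trunc_normal(rng, (out_ch, in_ch, kernel, kernel), std=std))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 padding: int = 0):
        super().__init__()
        std = math.sqrt(2.0 / (kernel * kernel))
        self.weight = Parameter(trunc_normal(rng, (channels, kernel, kernel), std=std))
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, padding=self.padding)


class Conv1dChannel(Module):
    """Bias-free 1-D convolution across the channel axis (the ECA kernel)."""

    def __init__(self, kernel: int, rng: np.random.Generator, bias: bool = False):
        super().__init__()
        std = math.sqrt(1.0 / kernel)
        self.weight = Parameter(trunc_normal(rng, (kernel,), std=std))
        self.bias = Parameter(np.zeros(1)) if bias else None

    def forward(self, z: Tensor) -> Tensor:
        return F.conv1d_channels(z, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=DTYPE))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    """Normalisation over the trailing (feature) axis of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta
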