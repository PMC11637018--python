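"""Network building blocks: convolutions, instance norm, CBAM attention.

All modules are thin containers of named parameters (``Tensor`` leaves with
``requires_grad=True``).  ``forward`` takes an optional ``rng`` and a
``training`` flag; dropout draws from ``rng`` only when training is on, so a
deterministic evaluation pass never consumes randomness.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigurationError

LEAKY_SLOPE = 0.01


class Module:
    """Base class: recursive named-parameter collection."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for attr, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[attr] = value
            elif isinstance(value, Module):
                for name, p in value.parameters().items():
                    params[f"{attr}.{name}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for name, p in item.parameters().items():
                            params[f"{attr}.{i}.{name}"] = p
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise ValueError(f"parameter set mismatch: {sorted(missing)[:5]}...")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


def _kaiming(rng: np.random.Generator, shape, fan_in: int,
             slope: float = LEAKY_SLOPE) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + slope ** 2))
    std = gain / np.sqrt(fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        if kernel % 2 == 0:
            raise ConfigurationError("convolution kernel must be odd")
        fan_in = cin * kernel ** 3
        self.weight = Tensor(_kaiming(rng, (cout, cin, kernel, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((channels, 1, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1, 1), dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = ag.square(xc).mean(axis=(1, 2, 3), keepdims=True)
        y = xc / ag.sqrt(var + self.eps)
        return self.gamma * y + self.beta


class ChannelAttention(Module):
    """Squeeze-style channel gate: sigmoid(MLP(maxpool) + MLP(avgpool)).

    The two global descriptors share one bottleneck MLP (reduction ratio r),
    with ReLU in the hidden layer and no biases.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if reduction > channels:
            raise ConfigurationError(
                f"channel-attention reduction {reduction} exceeds channel count {channels}")
        hidden = max(channels // reduction, 1)
        self.w1 = Tensor(_kaiming(rng, (channels, hidden), channels), requires_grad=True)
        self.w2 = Tensor(_kaiming(rng, (hidden, channels), hidden), requires_grad=True)

    def weights(self, x: Tensor) -> Tensor:
        """Per-channel gate values in (0,1), shape (C,)."""
        vmax = ag.reshape(ag.spatial_max(x), (1, -1))
        vavg = ag.reshape(x.mean(axis=(1, 2, 3)), (1, -1))
        branch_max = ag.matmul(ag.relu(ag.matmul(vmax, self.w1)), self.w2)
        branch_avg = ag.matmul(ag.relu(ag.matmul(vavg, self.w1)), self.w2)
        return ag.reshape(ag.sigmoid(branch_max + branch_avg), (-1,))

    def forward(self, x: Tensor) -> Tensor:
        w = ag.reshape(self.weights(x), (-1, 1, 1, 1))
        return x * w


class SpatialAttention(Module):
    """Spatial gate: sigmoid(conv([max_c(x); mean_c(x)])), one weight per voxel."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0 or kernel < 1:
            raise ConfigurationError("spatial-attention kernel must be odd and positive")
        self.conv = Conv3d(2, 1, kernel, rng, bias=True)

    def weights(self, x: Tensor) -> Tensor:
        """Spatial gate map in (0,1), shape (1, D, H, W)."""
        cmax = ag.channel_max(x)
        cavg = _channel_mean(x)
        return ag.sigmoid(self.conv.forward(ag.concat([cmax, cavg], axis=0)))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


def _channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[0]
    return ag.tsum(x, axis=0, keepdims=True) * (1.0 / c)


class CBAM(Module):
    """Channel attention followed (serially) by spatial attention."""

    def __init__(self, channels: int, reduction: int, kernel: int,
                 rng: np.random.Generator):
        self.cam = ChannelAttention(channels, reduction, rng)
        self.sam = SpatialAttention(kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.sam.forward(self.cam.forward(x))


class ConvBlock(Module):
    """Two (conv 3x3x3 -> InstanceNorm -> LeakyReLU) stages with optional
    residual shortcut (post-activation addition) and optional CBAM."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, *,
                 use_residual: bool, use_cbam: bool,
                 cam_reduction: int = 8, sam_kernel: int = 7):
        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.norm1 = InstanceNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.norm2 = InstanceNorm3d(cout)
        self.use_residual = use_residual
        self.shortcut = None
        if use_residual and cin != cout:
            self.shortcut = Conv3d(cin, cout, 1, rng, bias=False)
        self.cbam = CBAM(cout, min(cam_reduction, cout), sam_kernel, rng) if use_cbam else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.leaky_relu(self.norm1.forward(self.conv1.forward(x)), LEAKY_SLOPE)
        y = ag.leaky_relu(self.norm2.forward(self.conv2.forward(y)), LEAKY_SLOPE)
        if self.use_residual:
            skip = self.shortcut.forward(x) if self.shortcut is not None else x
            y = y + skip
        if self.cbam is not None:
            y = self.cbam.forward(y)
        return y
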