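"""Residual/attention 3D U-Net backbone.

The network is an encoder-decoder with max-pool downsampling and
nearest-neighbour-upsample + convolution decoding.  Two switches span the
ablation axis used throughout the package:

* ``use_residual`` — per-block residual shortcuts,
* ``use_cbam``     — a serial channel-then-spatial attention gate per block.

Both off gives the plain 3D U-Net baseline; residual only gives the
intermediate variant; both on gives the full residual-CBAM network.  Dropout
layers sit after every block group so the same graph supports Monte-Carlo
sampling at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigurationError
from .layers import Module, Conv3d, ConvBlock

__all__ = ["NetworkSpec", "UNet3D", "build_network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; the two booleans are the ablation axis."""

    in_channels: int = 1
    num_classes: int = 2
    levels: int = 3
    base_channels: int = 8
    use_residual: bool = True
    use_cbam: bool = True
    cam_reduction: int = 8
    sam_kernel: int = 7
    dropout_rate: float = 0.1
    bottleneck_dropout: float = 0.5

    def validate(self) -> None:
        if self.in_channels < 1 or self.num_classes < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.levels < 1 or self.base_channels < 1:
            raise ConfigurationError("levels and base_channels must be positive")
        if not 0.0 <= self.dropout_rate < 1.0 or not 0.0 <= self.bottleneck_dropout < 1.0:
            raise ConfigurationError("dropout rates must lie in [0,1)")
        if self.sam_kernel % 2 == 0 or self.sam_kernel < 1:
            raise ConfigurationError("sam_kernel must be odd and positive")
        if self.cam_reduction < 1:
            raise ConfigurationError("cam_reduction must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


class UNet3D(Module):
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng([int(seed) % (2 ** 31), 2210])
        kw = dict(use_residual=spec.use_residual, use_cbam=spec.use_cbam,
                  cam_reduction=spec.cam_reduction, sam_kernel=spec.sam_kernel)
        chans = [spec.base_channels * 2 ** l for l in range(spec.levels)]
        self.encoders = [ConvBlock(spec.in_channels if l == 0 else chans[l - 1],
                                   chans[l], rng, **kw)
                         for l in range(spec.levels - 1)]
        bottom_in = chans[-2] if spec.levels > 1 else spec.in_channels
        self.bottleneck = ConvBlock(bottom_in, chans[-1], rng, **kw)
        self.upconvs = [Conv3d(chans[l + 1], chans[l], 3, rng)
                        for l in range(spec.levels - 1)]
        self.decoders = [ConvBlock(2 * chans[l], chans[l], rng, **kw)
                         for l in range(spec.levels - 1)]
        self.head = Conv3d(chans[0] if spec.levels > 1 else chans[-1],
                           spec.num_classes, 1, rng)

    def _check_shape(self, x: np.ndarray) -> None:
        factor = 2 ** (self.spec.levels - 1)
        spatial = x.shape[1:]
        if min(spatial) < 2 ** self.spec.levels:
            raise ConfigurationError(
                f"volume {spatial} too small for {self.spec.levels} levels")
        if any(s % factor for s in spatial):
            raise ConfigurationError(
                f"spatial dims {spatial} must be divisible by {factor}")

    def forward(self, x, *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Raw class scores with the same spatial shape as the input.

        ``training=True`` activates dropout (requires ``rng``); this is also
        the stochastic mode used for Monte-Carlo uncertainty passes.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[0] != self.spec.in_channels:
            raise ConfigurationError(
                f"expected ({self.spec.in_channels}, D, H, W) input, got {x.shape}")
        self._check_shape(x.data)
        if training and rng is None:
            raise ConfigurationError("training-mode forward needs an rng for dropout")

        def drop(t: Tensor, rate: float) -> Tensor:
            if training and rate > 0.0:
                return ag.dropout(t, rate, rng)
            return t

        skips = []
        h = x
        for enc in self.encoders:
            h = drop(enc.forward(h), self.spec.dropout_rate)
            skips.append(h)
            h = ag.maxpool2(h)
        h = drop(self.bottleneck.forward(h), self.spec.bottleneck_dropout)
        for l in range(self.spec.levels - 2, -1, -1):
            h = self.upconvs[l].forward(ag.upsample_nearest2(h))
            h = ag.concat([skips[l], h], axis=0)
            h = drop(self.decoders[l].forward(h), self.spec.dropout_rate)
        return self.head.forward(h)

    def predict_proba(self, volume: np.ndarray) -> np.ndarray:
        """Deterministic softmax probabilities (dropout off, no graph)."""
        with ag.no_grad():
            logits = self.forward(volume, training=False)
            return ag.softmax(logits, axis=0).data


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet3D:
    """Construct the backbone described by ``spec`` (validated)."""
    return UNet3D(spec, seed=seed)
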