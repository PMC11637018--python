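"""Monte-Carlo-dropout uncertainty estimation.

The teacher network is run N times in stochastic mode (dropout active,
independent Gaussian input noise per pass).  Averaging the per-pass softmax
maps gives the mean class probability M_c; the voxelwise Shannon entropy of
M_c (in nats) is the uncertainty map U, bounded by ln(num_classes).  Voxels
with U below a threshold form the reliability mask that gates the
consistency loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from . import autograd as ag
from .errors import ConfigurationError

__all__ = ["ProbabilityStack", "UncertaintyMap", "mc_forward",
           "mean_probability", "entropy_uncertainty", "reliability_mask",
           "DEFAULT_MC_PASSES"]

#: number of stochastic forward passes used for uncertainty estimation
DEFAULT_MC_PASSES = 8
_NORM_TOL = 1e-5


@dataclass
class ProbabilityStack:
    """N per-pass softmax maps, shape (n_passes, num_classes, D, H, W)."""

    probs: np.ndarray
    n_passes: int
    num_classes: int

    def validate(self) -> None:
        if self.probs.ndim != 5:
            raise ConfigurationError("probability stack must be 5D")
        if self.probs.shape[0] != self.n_passes or self.probs.shape[1] != self.num_classes:
            raise ConfigurationError("stack shape disagrees with metadata")
        if self.probs.min() < -_NORM_TOL:
            raise ConfigurationError("negative probabilities in stack")
        sums = self.probs.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-4:
            raise ConfigurationError("per-voxel class probabilities must sum to 1")


@dataclass
class UncertaintyMap:
    mean_prob: np.ndarray   # (num_classes, D, H, W)
    entropy: np.ndarray     # (D, H, W), nats


@dataclass(frozen=True)
class NoiseSpec:
    """Additive input perturbation xi ~ N(0, sigma), clipped at +-clip."""

    sigma: float = 0.1
    clip: float = 0.2

    def apply(self, volume: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma <= 0:
            return volume
        noise = np.clip(self.sigma * rng.standard_normal(volume.shape),
                        -self.clip, self.clip).astype(volume.dtype)
        return volume + noise


def mc_forward(network, volume: np.ndarray, n_passes: int = DEFAULT_MC_PASSES,
               noise: NoiseSpec | None = None,
               rng: np.random.Generator | None = None,
               stochastic: bool = True) -> ProbabilityStack:
    """Stack of softmax maps from repeated perturbed forward passes.

    Each pass perturbs the input with an independent noise draw and an
    independent dropout realisation.  With ``stochastic=False`` and no noise
    the passes are identical deterministic forwards (degenerate MC).
    """
    if n_passes < 1:
        raise ConfigurationError("n_passes must be >= 1")
    noise = noise or NoiseSpec(sigma=0.0)
    if (stochastic or noise.sigma > 0) and rng is None:
        rng = np.random.default_rng(0)
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim == 3:
        vol = vol[None]
    outs = []
    with ag.no_grad():
        for _ in range(n_passes):
            x = noise.apply(vol, rng) if noise.sigma > 0 else vol
            logits = network.forward(x, training=stochastic, rng=rng)
            outs.append(ag.softmax(logits, axis=0).data)
    stack = ProbabilityStack(np.stack(outs).astype(np.float64),
                             n_passes=n_passes,
                             num_classes=network.spec.num_classes)
    stack.validate()
    return stack


def mean_probability(stack: ProbabilityStack) -> np.ndarray:
    """Voxelwise arithmetic mean over passes, per class (M_c)."""
    if stack.probs.shape[0] == 0:
        raise ConfigurationError("empty probability stack")
    stack.validate()
    return stack.probs.mean(axis=0)


def entropy_uncertainty(mean_prob: np.ndarray) -> np.ndarray:
    """Voxelwise Shannon entropy U = -sum_c M_c ln M_c (0 ln 0 := 0)."""
    mean_prob = np.asarray(mean_prob, dtype=np.float64)
    sums = mean_prob.sum(axis=0)
    if np.abs(sums - 1.0).max() > _NORM_TOL or mean_prob.min() < -_NORM_TOL:
        raise ValueError("mean probability map is not normalised")
    mp = np.clip(mean_prob, 0.0, None)  # guard float roundoff below 0
    return -xlogy(mp, mp).sum(axis=0)


def reliability_mask(entropy: np.ndarray, threshold: float) -> np.ndarray:
    """Indicator H(u < threshold): 1 on reliable (low-entropy) voxels."""
    if threshold < 0:
        raise ConfigurationError("uncertainty threshold must be >= 0")
    return (np.asarray(entropy) < threshold).astype(np.uint8)


def uncertainty_map(stack: ProbabilityStack) -> UncertaintyMap:
    mean = mean_probability(stack)
    return UncertaintyMap(mean_prob=mean, entropy=entropy_uncertainty(mean))
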