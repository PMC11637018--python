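"""Loss terms and schedules for semi-supervised mean-teacher training.

Supervised loss: unweighted mean of soft Dice loss (foreground classes) and
voxelwise cross-entropy.  Consistency loss: mean squared difference between
student and teacher softmax maps, averaged only over voxels whose teacher
uncertainty falls below the threshold (guarded against an empty mask).  The
consistency weight follows the standard Gaussian ramp
lambda(t) = lambda_max * exp(-5 (1 - t/T)^2) and plateaus after T steps; the
uncertainty threshold ramps from (3/4) ln(c) to ln(c) on the same schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigurationError

__all__ = ["LossConfig", "supervised_loss", "consistency_loss", "joint_loss",
           "lambda_schedule", "threshold_schedule"]


@dataclass(frozen=True)
class LossConfig:
    lambda_max: float = 0.1
    rampup_length: int = 100
    smooth: float = 1e-5

    def validate(self) -> None:
        if self.lambda_max < 0:
            raise ConfigurationError("lambda_max must be >= 0")
        if self.rampup_length < 1:
            raise ConfigurationError("rampup_length must be positive")
        if self.smooth <= 0:
            raise ConfigurationError("smooth must be positive")


def _ramp(step: int, length: int) -> float:
    t = min(max(step, 0), length) / length
    return float(np.exp(-5.0 * (1.0 - t) ** 2))


def lambda_schedule(step: int, cfg: LossConfig) -> float:
    """Consistency weight lambda(step) in [~0, lambda_max]."""
    cfg.validate()
    return cfg.lambda_max * _ramp(step, cfg.rampup_length)


def threshold_schedule(step: int, rampup_length: int, num_classes: int = 2) -> float:
    """Uncertainty gate I(step), ramping (3/4) ln(c) -> ln(c)."""
    umax = float(np.log(num_classes))
    return umax * (0.75 + 0.25 * _ramp(step, rampup_length))


def _as_tensor(x) -> Tensor:
    # Tensor preserves float dtype (float64 oracles stay float64)
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def supervised_loss(logits, labels, smooth: float = 1e-5) -> Tensor:
    """Mean of soft-Dice loss and cross-entropy against an integer label map.

    ``logits``: (c, D, H, W) raw scores; ``labels``: integer map in {0..c-1}.
    Dice is computed on softmax probabilities for each foreground class and
    averaged; both terms are nonnegative.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    c = logits.shape[0]
    if labels.shape != logits.shape[1:]:
        raise ValueError(f"label shape {labels.shape} != logits spatial {logits.shape[1:]}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    probs = ag.softmax(logits, axis=0)
    n = labels.size

    # cross-entropy: -mean log p at the true class
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    np.put_along_axis(onehot, labels[None].astype(np.int64), 1.0, axis=0)
    shift = Tensor(logits.data.max(axis=0, keepdims=True))
    logp = (logits - shift) - ag.log(ag.tsum(ag.exp(logits - shift), axis=0, keepdims=True))
    ce = -ag.tsum(logp * Tensor(onehot)) * (1.0 / n)

    # soft Dice over foreground classes
    dice_losses = []
    for k in range(1, c):
        pk = ag.narrow(probs, 0, k, 1)
        gk = Tensor((labels == k).astype(logits.data.dtype)[None])
        inter = ag.tsum(pk * gk)
        denom = ag.tsum(pk) + ag.tsum(gk)
        dice = (2.0 * inter + smooth) / (denom + smooth)
        dice_losses.append(1.0 - dice)
    if dice_losses:
        dl = dice_losses[0]
        for extra in dice_losses[1:]:
            dl = dl + extra
        dl = dl * (1.0 / len(dice_losses))
        return (ce + dl) * 0.5
    return ce


def consistency_loss(student_probs, teacher_probs, entropy, threshold: float):
    """Uncertainty-masked mean squared difference of probability maps.

    sum_i H(u_i < I) * mean_c (f_ic - f'_ic)^2 / sum_i H(u_i < I); returns 0
    when no voxel is reliable.  Differentiable in the student probabilities.
    """
    student_probs = _as_tensor(student_probs)
    teacher = np.asarray(teacher_probs, dtype=student_probs.data.dtype)
    entropy = np.asarray(entropy)
    if teacher.shape != student_probs.shape:
        raise ValueError("student and teacher probability shapes differ")
    if entropy.shape != student_probs.shape[1:]:
        raise ValueError("entropy map shape does not match spatial shape")
    mask = (entropy < threshold)
    m = float(mask.sum())
    if m == 0.0:
        return Tensor(np.zeros((), dtype=student_probs.data.dtype))
    c = student_probs.shape[0]
    w = (mask.astype(student_probs.data.dtype) / (m * c))[None]
    diff = student_probs - Tensor(teacher)
    return ag.tsum(ag.square(diff) * Tensor(w))


def joint_loss(sup, con, step: int, cfg: LossConfig):
    """Total objective: supervised + lambda(step) * consistency."""
    lam = lambda_schedule(step, cfg)
    if isinstance(sup, Tensor) or isinstance(con, Tensor):
        return _as_tensor(sup) + _as_tensor(con) * lam
    return float(sup) + lam * float(con)
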