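"""Differentiable training objectives.

Soft Dice, soft centerline-Dice, and the combined cascade loss

    L(S_P, S_G, C_P, C_G) = Dice(S_P, S_G)
                          + λ1 · Dice(C_P, C_G)
                          + λ2 · clDice(S_P, S_G, C_P, C_G)

where S is a segmentation, C a centerline, subscript P a prediction and
G a reference. All ratios carry an ε = 1e-5 smoothing term in numerator
and denominator so empty patches (common with sparse vessels) stay
finite; sums run over every voxel of the batch. Inputs may be numpy
arrays or autodiff Tensors; the loss is returned as a Tensor so that
gradients flow to both network outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autodiff import Tensor, as_tensor

__all__ = ["LossWeights", "soft_dice_loss", "soft_cl_dice_loss", "cascaded_loss", "EPSILON"]

EPSILON = 1e-5


@dataclass(frozen=True)
class LossWeights:
    """Weights of the skeleton-Dice (λ1) and clDice (λ2) terms; the tuned
    operating point for the frozen-skeleton cascade is λ1 = λ2 = 0.5."""

    lambda1: float = 0.5
    lambda2: float = 0.5

    def __post_init__(self):
        if not (self.lambda1 >= 0 and self.lambda2 >= 0):
            raise ValueError("loss weights must be finite and non-negative")


def _pair(pred, target, name):
    pred, target = as_tensor(pred), as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"{name}: shape mismatch {pred.shape} vs {target.shape}")
    return pred, target


def soft_dice_loss(pred, target, eps: float = EPSILON) -> Tensor:
    """1 − soft Dice: 1 − (2·Σ p·t + ε) / (Σ p + Σ t + ε)."""
    pred, target = _pair(pred, target, "soft_dice_loss")
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def soft_cl_dice_loss(S_P, S_G, C_P, C_G, eps: float = EPSILON) -> Tensor:
    """1 − soft clDice with elementwise-product intersections.

    Soft topology precision  = (Σ C_P·S_G + ε) / (Σ C_P + ε),
    soft topology sensitivity = (Σ C_G·S_P + ε) / (Σ C_G + ε),
    combined as their harmonic mean. Reduces to 1 − clDice on binary input.
    """
    S_P, S_G = _pair(S_P, S_G, "soft_cl_dice_loss (segmentations)")
    C_P, C_G = _pair(C_P, C_G, "soft_cl_dice_loss (centerlines)")
    if S_P.shape != C_P.shape:
        raise ValueError("segmentation and centerline shapes differ")
    tprec = ((C_P * S_G).sum() + eps) / (C_P.sum() + eps)
    tsens = ((C_G * S_P).sum() + eps) / (C_G.sum() + eps)
    return 1.0 - (2.0 * tprec * tsens) / (tprec + tsens)


def cascaded_loss(S_P, S_G, C_P, C_G, w: LossWeights = LossWeights()) -> Tensor:
    """Combined objective of the cascaded model; differentiable in both
    the predicted segmentation S_P and predicted centerline C_P."""
    loss = soft_dice_loss(S_P, S_G)
    if w.lambda1 != 0:
        loss = loss + w.lambda1 * soft_dice_loss(C_P, C_G)
    if w.lambda2 != 0:
        loss = loss + w.lambda2 * soft_cl_dice_loss(S_P, S_G, C_P, C_G)
    return loss
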