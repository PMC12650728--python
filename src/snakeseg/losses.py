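"""Combined Dice-Focal training objective.

Soft Dice optimizes region overlap directly; binary focal loss
down-weights easy pixels by (1 - p_t)^gamma and re-balances the rare
foreground with alpha, prioritizing hard samples such as fine branches.
The combined loss is the weighted sum of the two.  All losses are
computed on the foreground probability channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeError
from .nn import Tensor, as_tensor

__all__ = ["LossConfig", "dice_loss", "focal_loss", "combined_loss"]

_P_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    lambda_dice: float = 1.0
    lambda_focal: float = 1.0
    gamma: float = 2.0
    alpha: float = 0.25
    smooth: float = 1.0

    def __post_init__(self):
        if self.lambda_dice < 0 or self.lambda_focal < 0 or self.gamma < 0:
            raise ValueError("loss weights and gamma must be non-negative")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.smooth < 0:
            raise ValueError("smooth must be non-negative")


def _check(prob, target) -> tuple[Tensor, Tensor]:
    prob = as_tensor(prob)
    target = as_tensor(np.asarray(target.data if isinstance(target, Tensor) else target, dtype=np.float32))
    if prob.shape != target.shape:
        raise ShapeError(f"probability shape {prob.shape} != target shape {target.shape}")
    return prob, target


def dice_loss(prob, target, smooth: float = 1.0) -> Tensor:
    """1 - soft-Dice:  1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s)."""
    prob, target = _check(prob, target)
    inter = (prob * target).sum()
    denom = prob.sum() + target.sum() + smooth
    if smooth == 0 and float(denom.data) == 0.0:
        return as_tensor(np.float32(0.0))  # both empty: perfect overlap
    return 1.0 - (2.0 * inter + smooth) / denom


def focal_loss(prob, target, gamma: float = 2.0, alpha: float = 0.25) -> Tensor:
    """Mean over pixels of -alpha_t * (1 - p_t)^gamma * log(p_t).

    ``p_t`` is the predicted probability of the true class; probabilities
    are clamped to [1e-7, 1 - 1e-7] before the log.
    """
    prob, target = _check(prob, target)
    p = prob.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    pt = p * target + (1.0 - p) * (1.0 - target)
    at = alpha * target + (1.0 - alpha) * (1.0 - target)
    mod = (1.0 - pt) ** gamma if gamma != 0 else 1.0
    return -(at * mod * pt.log()).mean()


def combined_loss(prob, target, cfg: LossConfig = LossConfig()) -> Tensor:
    """lambda_dice * dice + lambda_focal * focal."""
    return cfg.lambda_dice * dice_loss(prob, target, cfg.smooth) + cfg.lambda_focal * focal_loss(
        prob, target, cfg.gamma, cfg.alpha
    )
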