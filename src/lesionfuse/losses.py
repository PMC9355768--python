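"""Differentiable training losses: Dice loss, Focal Tversky loss, and their fusion.

The Tversky index generalizes Dice with asymmetric penalties on false
negatives (weight alpha) and false positives (weight beta):

    TI = TP / (TP + alpha*FN + beta*FP)

computed on soft predictions (TP = sum p*t, FN = sum (1-p)*t, FP = sum p*(1-t))
with a small smoothing constant.  The focal Tversky loss raises the Tversky
deficit to a power gamma, FTL = (1 - TI)**gamma, which with gamma < 1
amplifies the gradient on hard, partially-segmented examples; gamma = 1
recovers the plain Tversky loss.  The fused training loss adds Dice loss
(1 - soft Dice) and FTL, combining Dice's region-overlap drive with the
Tversky asymmetry (alpha=0.7, beta=0.3) and focal shaping (gamma=0.75).

All functions accept numpy arrays (returning floats) or autodiff
:class:`~lesionfuse.nn.Tensor` values (returning Tensors) so the same code
scores predictions and drives backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn.tensor import Tensor, as_tensor

__all__ = [
    "TverskyParams", "tversky_index", "dice_loss", "focal_tversky_loss",
    "fusion_loss", "SMOOTH",
]

SMOOTH = 1e-6  # smoothing constant in all soft ratios


@dataclass(frozen=True)
class TverskyParams:
    """Weights of the Tversky index and focal exponent.

    alpha weights false negatives, beta false positives; alpha > beta biases
    the optimum toward recall.  gamma is the focal exponent of the FTL.
    """

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 0.75

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _maybe_item(value: Tensor, keep_tensor: bool):
    return value if keep_tensor else value.item()


def tversky_index(pred, truth, params: TverskyParams = TverskyParams(),
                  smooth: float = SMOOTH):
    """Soft Tversky index between a probability map and a binary mask."""
    keep = isinstance(pred, Tensor) or isinstance(truth, Tensor)
    p, t = as_tensor(pred), as_tensor(truth)
    tp = (p * t).sum()
    fn = ((1.0 - p) * t).sum()
    fp = (p * (1.0 - t)).sum()
    ti = (tp + smooth) / (tp + params.alpha * fn + params.beta * fp + smooth)
    return _maybe_item(ti, keep)


def dice_loss(pred, truth, smooth: float = SMOOTH):
    """1 - soft Dice, with soft Dice = (2*sum(p*t)+s) / (sum(p)+sum(t)+s)."""
    keep = isinstance(pred, Tensor) or isinstance(truth, Tensor)
    p, t = as_tensor(pred), as_tensor(truth)
    soft_dice = (2.0 * (p * t).sum() + smooth) / (p.sum() + t.sum() + smooth)
    return _maybe_item(1.0 - soft_dice, keep)


def focal_tversky_loss(pred, truth, params: TverskyParams = TverskyParams(),
                       smooth: float = SMOOTH, complement_power: bool = True):
    """Focal Tversky loss.

    ``complement_power=True`` (default) computes (1 - TI)**gamma, the focal
    form under which gamma=1 recovers the Tversky loss; ``False`` selects
    the alternative reading 1 - TI**gamma.
    """
    keep = isinstance(pred, Tensor) or isinstance(truth, Tensor)
    ti = tversky_index(as_tensor(pred), as_tensor(truth), params, smooth)
    if complement_power:
        loss = (1.0 - ti) ** params.gamma
    else:
        loss = 1.0 - ti**params.gamma
    return _maybe_item(loss, keep)


def fusion_loss(pred, truth, params: TverskyParams = TverskyParams(),
                w_dl: float = 1.0, w_ftl: float = 1.0, smooth: float = SMOOTH):
    """Fused training loss: ``w_dl * DiceLoss + w_ftl * FocalTverskyLoss``."""
    if w_dl < 0 or w_ftl < 0:
        raise ValueError("loss weights must be non-negative")
    keep = isinstance(pred, Tensor) or isinstance(truth, Tensor)
    p, t = as_tensor(pred), as_tensor(truth)
    total = w_dl * dice_loss(p, t, smooth) + \
        w_ftl * focal_tversky_loss(p, t, params, smooth)
    return _maybe_item(total, keep)
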