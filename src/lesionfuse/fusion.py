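"""Prediction fusion post-processing.

Each branch's thresholded prediction is first cleaned of small connected
components, then the two cleaned masks are combined.  Two concrete fusion
rules are provided:

* ``component_overlap`` (default): a connected component of one mask is
  retained iff the fraction of its pixels also predicted by the other mask
  reaches ``overlap_threshold``; the fused mask is the union of retained
  components from both sides.  This keeps whole mutually-confirmed regions.
* ``pixel_and``: the pixel-wise intersection — maximally conservative, so
  the fused mask can only lose false positives relative to either branch.

In both rules the fused mask is a subset of the union of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FusionConfig", "remove_small_components", "fuse_predictions",
    "postprocess_pipeline",
]

_STRATEGIES = ("pixel_and", "component_overlap")


@dataclass(frozen=True)
class FusionConfig:
    min_component_size: int = 64
    strategy: str = "component_overlap"
    overlap_threshold: float = 0.5
    connectivity: int = 8

    def __post_init__(self):
        if self.min_component_size < 0:
            raise ValueError("min_component_size must be non-negative")
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")
        if not 0 <= self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def remove_small_components(mask: np.ndarray, min_size: int,
                            connectivity: int = 8) -> np.ndarray:
    """Zero out every connected component smaller than ``min_size`` pixels."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    if min_size <= 1:
        return mask.astype(np.uint8)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return mask.astype(np.uint8)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels].astype(np.uint8)


def fuse_predictions(mask_a: np.ndarray, mask_b: np.ndarray,
                     cfg: FusionConfig = FusionConfig()) -> np.ndarray:
    """Combine two cleaned binary masks into the final segmentation."""
    mask_a = np.asarray(mask_a)
    mask_b = np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise ValueError(
            f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    if cfg.strategy == "pixel_and":
        return (a & b).astype(np.uint8)

    fused = np.zeros(a.shape, dtype=bool)
    structure = _structure(cfg.connectivity)
    for mask, other in ((a, b), (b, a)):
        labels, n = ndimage.label(mask, structure=structure)
        for comp in range(1, n + 1):
            members = labels == comp
            size = members.sum()
            overlap = (members & other).sum()
            if size and overlap / size >= cfg.overlap_threshold:
                fused |= members
    return fused.astype(np.uint8)


def postprocess_pipeline(prob_a: np.ndarray, prob_b: np.ndarray,
                         threshold: float = 0.5,
                         cfg: FusionConfig = FusionConfig()) -> np.ndarray:
    """Threshold both probability maps, clean them, and fuse."""
    prob_a = np.asarray(prob_a)
    prob_b = np.asarray(prob_b)
    if prob_a.shape != prob_b.shape:
        raise ValueError(f"shape mismatch: {prob_a.shape} vs {prob_b.shape}")
    mask_a = remove_small_components((prob_a > threshold).astype(np.uint8),
                                     cfg.min_component_size, cfg.connectivity)
    mask_b = remove_small_components((prob_b > threshold).astype(np.uint8),
                                     cfg.min_component_size, cfg.connectivity)
    return fuse_predictions(mask_a, mask_b, cfg)
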