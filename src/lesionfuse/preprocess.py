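"""Image enhancement chain applied before training and prediction.

Order: piecewise-linear percentile contrast stretch -> unsharp-mask
sharpening -> resize to the network input size -> RGB-to-luma conversion
(the networks consume single-channel input).  The stretch maps intensities
at or below the low percentile to 0 and at or above the high percentile to
255, linearly in between, making low-contrast lesions more prominent; the
unsharp mask counteracts fuzzy lesion borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .data import ImageMaskPair

__all__ = [
    "PreprocessConfig", "contrast_stretch", "sharpen", "resize_pair",
    "to_grayscale", "preprocess_pair",
]


@dataclass(frozen=True)
class PreprocessConfig:
    stretch_low_percentile: float = 2.0
    stretch_high_percentile: float = 98.0
    sharpen_amount: float = 10.0
    sharpen_sigma: float = 1.0
    target_size: tuple[int, int] = (512, 512)
    grayscale: bool = True

    def __post_init__(self):
        if not 0 <= self.stretch_low_percentile < self.stretch_high_percentile <= 100:
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        if min(self.target_size) <= 0:
            raise ValueError("target_size dimensions must be positive")
        if self.sharpen_amount < 0:
            raise ValueError("sharpen amount must be non-negative")


def _restore_dtype(out: np.ndarray, like: np.ndarray) -> np.ndarray:
    out = np.clip(out, 0, 255)
    if np.issubdtype(like.dtype, np.integer):
        return np.rint(out).astype(like.dtype)
    return out.astype(np.float64)


def contrast_stretch(image: np.ndarray,
                     cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Monotone piecewise-linear stretch of intensities onto [0, 255].

    Applied per channel on RGB input.  A constant image has no dynamic range
    to stretch and is returned unchanged with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")

    def stretch_channel(ch: np.ndarray) -> np.ndarray:
        lo = np.percentile(ch, cfg.stretch_low_percentile)
        hi = np.percentile(ch, cfg.stretch_high_percentile)
        if hi <= lo:
            warnings.warn("constant channel: contrast stretch is a no-op",
                          stacklevel=3)
            return ch.astype(np.float64)
        return np.clip((ch.astype(np.float64) - lo) / (hi - lo), 0, 1) * 255.0

    if image.ndim == 3:
        out = np.stack([stretch_channel(image[..., c])
                        for c in range(image.shape[2])], axis=-1)
    else:
        out = stretch_channel(image)
    return _restore_dtype(out, image)


def sharpen(image: np.ndarray, amount: float = 10.0,
            sigma: float = 1.0) -> np.ndarray:
    """Unsharp mask: ``clip(x + amount * (x - gaussian_blur(x)), 0, 255)``."""
    if amount < 0:
        raise ValueError("sharpen amount must be non-negative")
    image = np.asarray(image)
    x = image.astype(np.float64)
    if image.ndim == 3:
        blur = np.stack([gaussian_filter(x[..., c], sigma)
                         for c in range(image.shape[2])], axis=-1)
    else:
        blur = gaussian_filter(x, sigma)
    return _restore_dtype(x + amount * (x - blur), image)


def _resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if image.shape[:2] == tuple(size):
        return image
    out = resize(image.astype(np.float64), size, order=1, mode="reflect",
                 preserve_range=True, anti_aliasing=True)
    return _restore_dtype(out, image)


def _resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if mask.shape == tuple(size):
        return mask
    out = resize(mask, size, order=0, mode="edge", preserve_range=True,
                 anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def resize_pair(pair: ImageMaskPair,
                target_size: tuple[int, int] = (512, 512)) -> ImageMaskPair:
    """Bilinear resize of the image, nearest-neighbour resize of the mask."""
    return ImageMaskPair(
        id=pair.id,
        image=_resize_image(pair.image, target_size),
        mask=None if pair.mask is None else _resize_mask(pair.mask, target_size),
    )


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma; single-channel input passes through."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    luma = image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114
    return _restore_dtype(luma, image)


def preprocess_pair(pair: ImageMaskPair,
                    cfg: PreprocessConfig = PreprocessConfig()) -> ImageMaskPair:
    """Full enhancement chain: stretch -> sharpen -> resize -> luma."""
    image = contrast_stretch(pair.image, cfg)
    image = sharpen(image, cfg.sharpen_amount, cfg.sharpen_sigma)
    out = resize_pair(ImageMaskPair(pair.id, image, pair.mask), cfg.target_size)
    if cfg.grayscale:
        out = ImageMaskPair(out.id, to_grayscale(out.image), out.mask)
    return out
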