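"""Training-set augmentation: flips, rotation, distortion, elastic warps,
and boundary (lesion-edge) crops.

Every transform applies the same geometric map to the image (bilinear
interpolation) and the mask (nearest neighbour, so it stays binary).  All
randomness flows from one seeded generator, making a full augmented dataset
reproducible.  The boundary crop rescales the pair, crops a window centred
on a randomly chosen lesion-edge pixel, and resizes it back to the original
frame — training material aimed specifically at edge localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize, rescale

from .data import ImageMaskPair
from .preprocess import resize_pair

__all__ = [
    "AugmentConfig", "flip", "rotate_pair", "random_rotation",
    "elastic_transform", "random_distortion", "boundary_crop",
    "augment_dataset",
]


@dataclass(frozen=True)
class AugmentConfig:
    rotation_range: float = 30.0        # degrees, sampled in [-r, r]
    distortion_grid: int = 4            # grid cells per side
    distortion_magnitude: float = 8.0   # px
    elastic_alpha: float = 30.0         # px, displacement amplitude
    elastic_sigma: float = 4.0          # px, displacement smoothness
    boundary_crop_size: int = 64        # px
    boundary_scale_range: tuple[float, float] = (0.8, 1.2)
    multiplier: int = 5
    transform_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if min(self.rotation_range, self.distortion_magnitude,
               self.elastic_alpha, self.elastic_sigma) < 0:
            raise ValueError("magnitudes must be non-negative")
        if self.distortion_grid < 2:
            raise ValueError("distortion grid must be >= 2")


def _warp_pair(pair: ImageMaskPair, row_coords: np.ndarray,
               col_coords: np.ndarray) -> ImageMaskPair:
    """Resample image (bilinear) and mask (nearest) at the given coordinates."""
    coords = np.stack([row_coords, col_coords])

    def warp_channel(ch, order):
        return ndimage.map_coordinates(ch.astype(np.float64), coords,
                                       order=order, mode="reflect")

    img = pair.image
    if img.ndim == 3:
        image = np.stack([warp_channel(img[..., c], 1)
                          for c in range(img.shape[2])], axis=-1)
    else:
        image = warp_channel(img, 1)
    if np.issubdtype(img.dtype, np.integer):
        image = np.clip(np.rint(image), 0, 255).astype(img.dtype)
    mask = None
    if pair.mask is not None:
        mask = warp_channel(pair.mask, 0)
        mask = (mask > 0.5).astype(np.uint8)
    return ImageMaskPair(pair.id, image, mask)


def flip(pair: ImageMaskPair, axis: str) -> ImageMaskPair:
    """Mirror image and mask together; ``axis`` is 'horizontal' or 'vertical'.

    A horizontal flip mirrors left-right (flips columns); vertical mirrors
    top-bottom (flips rows).
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    np_axis = 1 if axis == "horizontal" else 0
    return ImageMaskPair(
        id=pair.id,
        image=np.flip(pair.image, axis=np_axis).copy(),
        mask=None if pair.mask is None else np.flip(pair.mask, axis=np_axis).copy(),
    )


def rotate_pair(pair: ImageMaskPair, angle: float) -> ImageMaskPair:
    """Rotate by ``angle`` degrees about the centre, size preserved."""
    if angle == 0:
        return pair
    image = ndimage.rotate(pair.image.astype(np.float64), angle, axes=(1, 0),
                           reshape=False, order=1, mode="reflect")
    if np.issubdtype(pair.image.dtype, np.integer):
        image = np.clip(np.rint(image), 0, 255).astype(pair.image.dtype)
    mask = None
    if pair.mask is not None:
        mask = ndimage.rotate(pair.mask, angle, axes=(1, 0), reshape=False,
                              order=0, mode="reflect")
        mask = (mask > 0.5).astype(np.uint8)
    return ImageMaskPair(pair.id, image, mask)


def random_rotation(pair: ImageMaskPair, angle_range: float,
                    rng: np.random.Generator) -> ImageMaskPair:
    return rotate_pair(pair, float(rng.uniform(-angle_range, angle_range)))


def elastic_transform(pair: ImageMaskPair, alpha: float, sigma: float,
                      rng: np.random.Generator) -> ImageMaskPair:
    """Gaussian-smoothed random displacement field, identical for image & mask."""
    if alpha < 0 or sigma < 0:
        raise ValueError("alpha and sigma must be non-negative")
    h, w = pair.shape
    # draw fields even for alpha=0 to keep downstream rng state consistent
    drow = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dcol = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    if alpha == 0:
        return pair
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return _warp_pair(pair, rows + drow, cols + dcol)


def random_distortion(pair: ImageMaskPair, grid: int, magnitude: float,
                      rng: np.random.Generator) -> ImageMaskPair:
    """Grid-based local warping: coarse random displacements, upsampled."""
    if grid < 2:
        raise ValueError("grid must be >= 2")
    h, w = pair.shape
    coarse = rng.uniform(-1, 1, (2, grid + 1, grid + 1)) * magnitude
    if magnitude == 0:
        return pair
    # interior control points move; the frame stays pinned
    coarse[:, 0, :] = coarse[:, -1, :] = coarse[:, :, 0] = coarse[:, :, -1] = 0
    drow = resize(coarse[0], (h, w), order=1, mode="edge")
    dcol = resize(coarse[1], (h, w), order=1, mode="edge")
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return _warp_pair(pair, rows + drow, cols + dcol)


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Lesion pixels with at least one background 4-neighbour; (k, 2) array."""
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask.astype(bool), structure=cross,
                                    border_value=1)
    return np.argwhere(mask.astype(bool) & ~eroded)


def boundary_crop(pair: ImageMaskPair, crop_size: int, scale: float,
                  rng: np.random.Generator) -> ImageMaskPair:
    """Crop around a random lesion-boundary pixel after rescaling by ``scale``.

    The crop is resized back to the original frame so augmented pairs keep a
    uniform shape.  Guaranteed to contain both lesion and background pixels.
    """
    if pair.mask is None:
        raise ValueError("boundary crop requires a mask")
    h, w = pair.shape
    image = rescale(pair.image.astype(np.float64), scale, order=1,
                    mode="reflect", channel_axis=2 if pair.image.ndim == 3 else None,
                    preserve_range=True, anti_aliasing=scale < 1)
    mask = rescale(pair.mask, scale, order=0, mode="edge",
                   preserve_range=True, anti_aliasing=False)
    mask = (mask > 0.5).astype(np.uint8)
    boundary = _boundary_pixels(mask)
    if len(boundary) == 0:
        raise ValueError(
            f"{pair.id}: mask has no lesion boundary (empty or full frame)")
    hh, ww = mask.shape
    half = crop_size // 2
    order = rng.permutation(len(boundary))
    for k in order:
        r, c = boundary[k]
        r0 = int(np.clip(r - half, 0, max(hh - crop_size, 0)))
        c0 = int(np.clip(c - half, 0, max(ww - crop_size, 0)))
        m = mask[r0:r0 + crop_size, c0:c0 + crop_size]
        if 0 < m.sum() < m.size:  # both classes present
            img = image[r0:r0 + crop_size, c0:c0 + crop_size]
            out = ImageMaskPair(pair.id,
                                np.clip(img, 0, 255).astype(pair.image.dtype)
                                if np.issubdtype(pair.image.dtype, np.integer)
                                else img,
                                m)
            return resize_pair(out, (h, w))
    raise ValueError(f"{pair.id}: no crop containing both classes found")


def augment_dataset(pairs: list[ImageMaskPair],
                    cfg: AugmentConfig = AugmentConfig()) -> list[ImageMaskPair]:
    """Expand ``pairs`` to ``multiplier * len(pairs)`` pairs.

    The originals are kept; each extra pair applies an independent random
    chain over the five transforms (each drawn with
    ``transform_probability``, in the fixed order flips -> rotation ->
    distortion -> elastic -> boundary crop).  Deterministic under
    ``cfg.seed``.
    """
    if not pairs:
        raise ValueError("no pairs to augment")
    rng = np.random.default_rng(cfg.seed)
    out = list(pairs)
    n_extra = (cfg.multiplier - 1) * len(pairs)
    for k in range(n_extra):
        src = pairs[k % len(pairs)]
        aug = ImageMaskPair(f"{src.id}_aug{k // len(pairs)}", src.image, src.mask)
        p = cfg.transform_probability
        if rng.random() < p:
            aug = flip(aug, "horizontal")
        if rng.random() < p:
            aug = flip(aug, "vertical")
        if rng.random() < p:
            aug = random_rotation(aug, cfg.rotation_range, rng)
        if rng.random() < p:
            aug = random_distortion(aug, cfg.distortion_grid,
                                    cfg.distortion_magnitude, rng)
        if rng.random() < p:
            aug = elastic_transform(aug, cfg.elastic_alpha, cfg.elastic_sigma, rng)
        if rng.random() < p and aug.mask is not None:
            if 0 < aug.mask.sum() < aug.mask.size:
                scale = rng.uniform(*cfg.boundary_scale_range)
                aug = boundary_crop(aug, cfg.boundary_crop_size, scale, rng)
        out.append(aug)
    return out
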