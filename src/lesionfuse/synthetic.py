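"""Synthetic dermoscopy-like image/mask generator.

Emulates the features that make real dermoscopy segmentation hard: a
skin-toned background with sensor noise, one lesion per image that is darker
than the surrounding skin by a controllable contrast, an irregular
star-convex border (a radial function r(theta) perturbed by smooth periodic
noise), and dark curvilinear hair-like artifacts drawn over the image but
never into the ground-truth mask.

Star-convexity guarantees a single connected lesion component with a known
analytic area, which the tests exploit; contrast and noise form a difficulty
dial (contrast 0.8 / no noise is trivially separable by thresholding,
contrast 0.1 / heavy noise is not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import bezier_curve

from .data import ImageMaskPair

__all__ = ["SynthConfig", "generate_pair", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    size: int = 128
    lesion_radius_range: tuple[float, float] = (0.15, 0.35)  # fraction of size
    border_irregularity: float = 0.25  # amplitude of radial perturbation
    contrast: float = 0.5              # lesion-to-skin intensity gap in [0, 1]
    n_hairs: int = 3
    noise_sigma: float = 8.0           # 8-bit intensity units
    rgb: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("lesion_radius_range must lie within (0, 0.5)")
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must be in [0, 1]")
        if self.n_hairs < 0 or self.noise_sigma < 0:
            raise ValueError("n_hairs and noise_sigma must be non-negative")


# skin and lesion chromaticity (8-bit RGB), roughly a light phototype
_SKIN_RGB = np.array([224.0, 172.0, 150.0])
_LESION_RGB = np.array([120.0, 82.0, 62.0])
_HAIR_VALUE = 30.0


def _radial_profile(rng: np.random.Generator, irregularity: float):
    """Smooth periodic perturbation f(theta) in [-1, 1], scaled by amplitude."""
    harmonics = np.arange(2, 7)
    amp = rng.normal(size=harmonics.size)
    phase = rng.uniform(0, 2 * np.pi, size=harmonics.size)

    def profile(theta: np.ndarray) -> np.ndarray:
        f = np.zeros_like(theta)
        for k, a, ph in zip(harmonics, amp, phase):
            f += a * np.cos(k * theta + ph)
        peak = np.abs(f).max()
        if peak > 0:
            f = f / peak
        return irregularity * f

    return profile


def generate_pair(cfg: SynthConfig, rng: np.random.Generator) -> ImageMaskPair:
    """One image/mask pair drawn from ``cfg`` using ``rng``."""
    n = cfg.size
    r0 = rng.uniform(*cfg.lesion_radius_range) * n
    r_max = r0 * (1 + cfg.border_irregularity)
    if r_max >= n / 2:
        raise ValueError(
            f"lesion radius {r_max:.1f}px would exceed the {n}px frame")
    margin = n / 2 - r_max
    cy = n / 2 + rng.uniform(-margin, margin) * 0.8
    cx = n / 2 + rng.uniform(-margin, margin) * 0.8

    profile = _radial_profile(rng, cfg.border_irregularity)
    yy, xx = np.mgrid[:n, :n]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    radius = r0 * (1 + profile(theta))
    mask = (np.hypot(dy, dx) <= radius).astype(np.uint8)

    base = rng.uniform(0.88, 1.0)  # per-image skin brightness factor
    lesion_frac = mask.astype(np.float64)
    # soften the lesion edge in the image only; the mask stays exact
    lesion_soft = gaussian_filter(lesion_frac, 1.0)

    if cfg.rgb:
        skin = _SKIN_RGB * base
        lesion = skin + (_LESION_RGB - skin) * cfg.contrast
        image = skin[None, None, :] + \
            (lesion - skin)[None, None, :] * lesion_soft[..., None]
    else:
        skin_value = 200.0 * base
        lesion_value = skin_value * (1 - cfg.contrast)
        image = skin_value + (lesion_value - skin_value) * lesion_soft

    hair_layer = np.zeros((n, n))
    for _ in range(cfg.n_hairs):
        pts = rng.uniform(0, n - 1, size=(3, 2))
        rr, cc = bezier_curve(int(pts[0, 0]), int(pts[0, 1]),
                              int(pts[1, 0]), int(pts[1, 1]),
                              int(pts[2, 0]), int(pts[2, 1]), weight=1.0,
                              shape=(n, n))
        hair_layer[rr, cc] = 1.0
    if cfg.n_hairs:
        hair_layer = np.clip(gaussian_filter(hair_layer, 0.6) * 2.5, 0, 1)
        if cfg.rgb:
            image = image * (1 - hair_layer[..., None]) \
                + _HAIR_VALUE * hair_layer[..., None]
        else:
            image = image * (1 - hair_layer) + _HAIR_VALUE * hair_layer

    if cfg.noise_sigma > 0:
        image = image + rng.normal(0, cfg.noise_sigma, size=image.shape)

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    pair_id = f"SYN{rng.integers(0, 10**8):08d}"
    return ImageMaskPair(id=pair_id, image=image, mask=mask)


def generate_dataset(n: int, cfg: SynthConfig = SynthConfig(),
                     seed: int | None = None) -> list[ImageMaskPair]:
    """``n`` independent pairs; reproducible under ``seed`` (default cfg.seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    pairs = []
    for i, child in enumerate(root.spawn(n)):
        pair = generate_pair(cfg, np.random.default_rng(child))
        pairs.append(ImageMaskPair(f"SYN{i:05d}", pair.image, pair.mask))
    return pairs
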