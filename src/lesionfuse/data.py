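"""Image/mask pair handling: loading, pairing by identifier, splitting, saving.

Follows the ISIC directory convention: an image ``<id>.jpg`` (or ``.png``) is
paired with a mask ``<id>_segmentation.png``.  Masks are binarized at load
(threshold 128 on 8-bit values) so that lossy-compressed masks still come out
as clean {0, 1} arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ImageMaskPair", "DatasetSplit", "load_pairs", "split_dataset",
    "save_mask", "load_mask", "save_pairs",
]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")
MASK_THRESHOLD = 128  # 8-bit values >= this are lesion


@dataclass
class ImageMaskPair:
    """One dermoscopy image with its binary lesion mask.

    ``image`` is (H, W) or (H, W, 3) with intensities in [0, 255]; ``mask``
    is (H, W) with values in {0, 1}, or ``None`` at prediction time.
    """

    id: str
    image: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim not in (2, 3):
            raise ValueError(f"{self.id}: image must be 2-D or 3-D (H,W[,3])")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError(
                    f"{self.id}: mask shape {self.mask.shape} does not match "
                    f"image shape {self.image.shape[:2]}")
            values = np.unique(self.mask)
            if not np.isin(values, (0, 1)).all():
                raise ValueError(f"{self.id}: mask must contain only 0 and 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class DatasetSplit:
    """Disjoint train/test partition of a pair list."""

    train: list[ImageMaskPair]
    test: list[ImageMaskPair]
    seed: int = 0

    def __post_init__(self):
        overlap = {p.id for p in self.train} & {p.id for p in self.test}
        if overlap:
            raise ValueError(f"train/test overlap on ids: {sorted(overlap)[:5]}")


def _read_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if "A" in im.mode or im.mode == "P" else "L")
            return np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable image file {path}: {exc}") from exc


def load_mask(path: Path | str) -> np.ndarray:
    """Load a mask image and binarize it (>= 128 -> 1)."""
    arr = _read_image(Path(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return (arr >= MASK_THRESHOLD).astype(np.uint8)


def load_pairs(image_dir: Path | str, mask_dir: Path | str | None = None,
               mask_suffix: str = "_segmentation") -> list[ImageMaskPair]:
    """Load all image/mask pairs from a directory tree.

    Images without a matching mask are skipped with a warning; a mask whose
    size differs from its image is an error.
    """
    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir) if mask_dir is not None else image_dir
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory {image_dir} does not exist")
    if not mask_dir.is_dir():
        raise FileNotFoundError(f"mask directory {mask_dir} does not exist")

    image_paths = sorted(
        p for p in image_dir.iterdir()
        if p.suffix.lower() in IMAGE_EXTENSIONS and mask_suffix not in p.stem
    )
    if not image_paths:
        raise FileNotFoundError(f"no images found in {image_dir}")

    pairs, orphans = [], []
    for img_path in image_paths:
        stem = img_path.stem
        mask_path = None
        for ext in IMAGE_EXTENSIONS:
            candidate = mask_dir / f"{stem}{mask_suffix}{ext}"
            if candidate.exists():
                mask_path = candidate
                break
        if mask_path is None:
            orphans.append(stem)
            continue
        image = _read_image(img_path)
        mask = load_mask(mask_path)
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"id {stem}: mask size {mask.shape} != image size {image.shape[:2]}")
        pairs.append(ImageMaskPair(id=stem, image=image, mask=mask))
    if orphans:
        warnings.warn(
            f"skipped {len(orphans)} image(s) without a mask: {orphans}",
            stacklevel=2)
    return pairs


def split_dataset(pairs: list[ImageMaskPair], test_fraction: float,
                  seed: int) -> DatasetSplit:
    """Deterministic random partition; ``|test| = round(test_fraction * n)``.

    With the 2594-image ISIC training set and ``test_fraction=0.2`` this
    reproduces the 2075 / 519 split.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    n_test = round(test_fraction * len(pairs))
    order = np.random.default_rng(seed).permutation(len(pairs))
    test_idx = set(order[:n_test].tolist())
    train = [p for i, p in enumerate(pairs) if i not in test_idx]
    test = [p for i, p in enumerate(pairs) if i in test_idx]
    return DatasetSplit(train=train, test=test, seed=seed)


def save_mask(mask: np.ndarray, path: Path | str) -> None:
    """Write a binary mask as a single-channel PNG with values {0, 255}."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def save_pairs(pairs: list[ImageMaskPair], out_dir: Path | str,
               mask_suffix: str = "_segmentation") -> None:
    """Write pairs in the ISIC layout (``<id>.png`` + ``<id><suffix>.png``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        img = np.clip(np.rint(pair.image), 0, 255).astype(np.uint8)
        Image.fromarray(img).save(out_dir / f"{pair.id}.png")
        if pair.mask is not None:
            save_mask(pair.mask, out_dir / f"{pair.id}{mask_suffix}.png")
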