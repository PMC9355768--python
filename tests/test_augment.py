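"""Augmentation tests: geometric consistency, binarity, reproducibility."""

import numpy as np
import pytest
from scipy import ndimage

from lesionfuse.augment import (
    AugmentConfig, augment_dataset, boundary_crop, elastic_transform, flip,
    random_distortion, random_rotation, rotate_pair,
)
from lesionfuse.data import ImageMaskPair
from lesionfuse.synthetic import SynthConfig, generate_pair


def test_flip_involution(lesion_pair):
    for axis in ("horizontal", "vertical"):
        twice = flip(flip(lesion_pair, axis), axis)
        assert np.array_equal(twice.image, lesion_pair.image)
        assert np.array_equal(twice.mask, lesion_pair.mask)
    with pytest.raises(ValueError):
        flip(lesion_pair, "diagonal")


def test_flip_symmetric_image_invariant():
    img = np.zeros((8, 8))
    img[:, 3:5] = 9.0  # mirror-symmetric about the vertical axis
    pair = ImageMaskPair("s", img, (img > 0).astype(np.uint8))
    assert np.array_equal(flip(pair, "horizontal").image, img)


def test_flip_mirrors_lesion_centroid(lesion_pair):
    c_before = ndimage.center_of_mass(lesion_pair.mask)
    c_after = ndimage.center_of_mass(flip(lesion_pair, "horizontal").mask)
    width = lesion_pair.mask.shape[1]
    assert c_after[1] == pytest.approx(width - 1 - c_before[1], abs=1e-9)
    assert c_after[0] == pytest.approx(c_before[0], abs=1e-9)


def test_rotation_identity_and_180(lesion_pair):
    assert np.array_equal(rotate_pair(lesion_pair, 0).image, lesion_pair.image)
    r180 = rotate_pair(lesion_pair, 180)
    both_flips = flip(flip(lesion_pair, "horizontal"), "vertical")
    assert np.array_equal(r180.mask, both_flips.mask)
    assert np.array_equal(r180.image, both_flips.image)


def test_random_rotation_deterministic(lesion_pair):
    a = random_rotation(lesion_pair, 30, np.random.default_rng(3))
    b = random_rotation(lesion_pair, 30, np.random.default_rng(3))
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)
    assert set(np.unique(a.mask)) <= {0, 1}


def test_elastic_identity_determinism_binarity(disc_pair):
    e0 = elastic_transform(disc_pair, 0, 4, np.random.default_rng(0))
    assert np.array_equal(e0.image, disc_pair.image)
    a = elastic_transform(disc_pair, 30, 4, np.random.default_rng(5))
    b = elastic_transform(disc_pair, 30, 4, np.random.default_rng(5))
    assert np.array_equal(a.image, b.image)
    assert set(np.unique(a.mask)) <= {0, 1}


def test_elastic_area_stability_on_disc(disc_pair):
    """Displacement fields (alpha=30, sigma=4) barely change the disc area."""
    base_area = int(disc_pair.mask.sum())
    worst = max(
        abs(int(elastic_transform(disc_pair, 30, 4,
                                  np.random.default_rng(s)).mask.sum())
            - base_area) / base_area
        for s in range(100))
    assert worst < 0.20


def test_distortion_identity_and_binarity(disc_pair):
    d0 = random_distortion(disc_pair, 4, 0, np.random.default_rng(0))
    assert np.array_equal(d0.image, disc_pair.image)
    d = random_distortion(disc_pair, 4, 8, np.random.default_rng(1))
    assert set(np.unique(d.mask)) <= {0, 1}
    d2 = random_distortion(disc_pair, 4, 8, np.random.default_rng(1))
    assert np.array_equal(d.image, d2.image)
    with pytest.raises(ValueError):
        random_distortion(disc_pair, 1, 8, np.random.default_rng(0))


def test_image_and_mask_share_the_geometric_map(disc_pair):
    """A coordinate-encoded image must move exactly with its mask."""
    coded = ImageMaskPair(
        "coded",
        disc_pair.mask.astype(np.float64) * 200.0,
        disc_pair.mask,
    )
    for transform in (
            lambda p: flip(p, "horizontal"),
            lambda p: random_rotation(p, 45, np.random.default_rng(2)),
            lambda p: random_distortion(p, 4, 6, np.random.default_rng(2)),
    ):
        out = transform(coded)
        # wherever the mask says lesion, the warped image must be bright
        inside = out.image[out.mask == 1]
        outside = out.image[out.mask == 0]
        assert inside.mean() > 150
        assert outside.mean() < 50


@pytest.mark.parametrize("scale", [0.8, 1.0, 1.2])
def test_boundary_crop_contains_both_classes(disc_pair, scale):
    out = boundary_crop(disc_pair, 64, scale, np.random.default_rng(4))
    assert out.mask.shape == disc_pair.mask.shape  # resized back
    assert 0 < out.mask.sum() < out.mask.size


def test_boundary_crop_centres_on_the_rim():
    """With an exactly centred disc (no window clamping) the crop centre
    sits on the lesion rim, so both classes appear right at the centre."""
    from lesionfuse.augment import _boundary_pixels
    yy, xx = np.mgrid[:128, :128]
    mask = (np.hypot(yy - 64, xx - 64) <= 32).astype(np.uint8)
    pair = ImageMaskPair("centred", mask * 150.0, mask)
    boundary = set(map(tuple, _boundary_pixels(mask)))
    assert boundary  # the disc has a rim
    rng = np.random.default_rng(0)
    for _ in range(5):
        out = boundary_crop(pair, 64, 1.0, rng)
        h, w = out.mask.shape
        window = out.mask[h // 2 - 8:h // 2 + 8, w // 2 - 8:w // 2 + 8]
        assert 0 < window.sum() < window.size


def test_boundary_crop_rejects_degenerate_masks(disc_pair):
    empty = ImageMaskPair("e", disc_pair.image,
                          np.zeros_like(disc_pair.mask))
    full = ImageMaskPair("f", disc_pair.image,
                         np.ones_like(disc_pair.mask))
    for bad in (empty, full):
        with pytest.raises(ValueError, match="boundary"):
            boundary_crop(bad, 32, 1.0, np.random.default_rng(0))


def test_augment_dataset_counts_and_determinism():
    pairs = [generate_pair(SynthConfig(size=64), np.random.default_rng(i))
             for i in range(4)]
    cfg = AugmentConfig(multiplier=3, seed=77)
    out1 = augment_dataset(pairs, cfg)
    out2 = augment_dataset(pairs, cfg)
    assert len(out1) == 12
    for a, b in zip(out1, out2):
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
        assert set(np.unique(a.mask)) <= {0, 1}
        assert a.image.shape[:2] == a.mask.shape
    only_originals = augment_dataset(pairs, AugmentConfig(multiplier=1))
    assert [p.id for p in only_originals] == [p.id for p in pairs]
    with pytest.raises(ValueError):
        AugmentConfig(multiplier=0)
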