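"""Fusion post-processing vs an independent recursive flood-fill oracle."""

import numpy as np
import pytest

from conftest import random_binary_mask
from lesionfuse.fusion import (
    FusionConfig, fuse_predictions, postprocess_pipeline,
    remove_small_components,
)
from lesionfuse.metrics import confusion_counts, specificity


def _flood_fill_components(mask: np.ndarray, connectivity: int):
    """Independent labelling oracle: iterative flood fill, no scipy."""
    h, w = mask.shape
    if connectivity == 4:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, members = [(r, c)], []
                seen[r, c] = True
                while stack:
                    cr, cc = stack.pop()
                    members.append((cr, cc))
                    for dr, dc in moves:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                components.append(members)
    return components


def _oracle_remove_small(mask, min_size, connectivity):
    out = np.zeros_like(mask)
    for members in _flood_fill_components(mask, connectivity):
        if len(members) >= min_size:
            for r, c in members:
                out[r, c] = 1
    return out


@pytest.mark.parametrize("connectivity", [4, 8])
def test_remove_small_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(99)
    for _ in range(200):
        mask = random_binary_mask(rng, (32, 32), p=rng.uniform(0.2, 0.6))
        min_size = int(rng.integers(1, 20))
        ours = remove_small_components(mask, min_size, connectivity)
        oracle = _oracle_remove_small(mask, min_size, connectivity)
        assert np.array_equal(ours, oracle)


def test_remove_small_basic_examples():
    mask = np.zeros((20, 20), np.uint8)
    mask[2:12, 2:12] = 1      # 100 px
    mask[15:18, 15:16] = 1    # 3 px
    cleaned = remove_small_components(mask, 10)
    assert cleaned.sum() == 100
    assert remove_small_components(np.zeros((5, 5), np.uint8), 10).sum() == 0
    assert np.array_equal(remove_small_components(mask, 0), mask)
    with pytest.raises(ValueError):
        remove_small_components(np.full((3, 3), 5), 10)


def test_connectivity_distinguishes_diagonal_touch():
    mask = np.zeros((4, 4), np.uint8)
    mask[0, 0] = mask[1, 1] = 1  # diagonal pair
    # 8-connectivity: one 2-px component survives min_size=2
    assert remove_small_components(mask, 2, connectivity=8).sum() == 2
    # 4-connectivity: two 1-px components, both removed
    assert remove_small_components(mask, 2, connectivity=4).sum() == 0


def test_fuse_idempotent_and_disjoint(rng):
    mask = random_binary_mask(rng, (16, 16))
    for strategy in ("pixel_and", "component_overlap"):
        cfg = FusionConfig(strategy=strategy)
        assert np.array_equal(fuse_predictions(mask, mask, cfg), mask)
    a = np.zeros((8, 8), np.uint8)
    b = np.zeros((8, 8), np.uint8)
    a[:2, :2] = 1
    b[5:, 5:] = 1
    assert fuse_predictions(a, b, FusionConfig(strategy="pixel_and")).sum() == 0
    assert fuse_predictions(
        a, b, FusionConfig(strategy="component_overlap",
                           overlap_threshold=0.5)).sum() == 0


def test_fuse_component_overlap_retention_rule():
    a = np.zeros((10, 10), np.uint8)
    a[0:2, 0:5] = 1  # one 10-px component
    b = np.zeros((10, 10), np.uint8)
    b[0:2, 0:3] = 1  # overlaps 6 of those 10 pixels
    fused = fuse_predictions(a, b, FusionConfig(strategy="component_overlap",
                                                overlap_threshold=0.5))
    assert fused.sum() == 10  # whole component retained (6/10 >= 0.5)
    anded = fuse_predictions(a, b, FusionConfig(strategy="pixel_and"))
    assert anded.sum() == 6
    # a stricter threshold drops A's component but keeps B's (6/6 overlap)
    strict = fuse_predictions(a, b, FusionConfig(strategy="component_overlap",
                                                 overlap_threshold=0.7))
    assert np.array_equal(strict, b)


def test_fuse_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        fuse_predictions(np.zeros((4, 4)), np.zeros((5, 5)))


@pytest.mark.parametrize("strategy", ["pixel_and", "component_overlap"])
def test_fused_subset_of_union_fuzzed(strategy):
    rng = np.random.default_rng(5)
    cfg = FusionConfig(strategy=strategy)
    for _ in range(200):
        a = random_binary_mask(rng, (24, 24), p=rng.uniform(0.1, 0.5))
        b = random_binary_mask(rng, (24, 24), p=rng.uniform(0.1, 0.5))
        fused = fuse_predictions(a, b, cfg)
        assert not np.any(fused & ~(a | b))
        if strategy == "pixel_and":
            assert not np.any(fused & ~a)
            assert not np.any(fused & ~b)


def test_pixel_and_bounds_false_positives(rng):
    """Intersection can only shed FPs, so fused FP <= min branch FP and
    fused specificity >= max branch specificity, for any ground truth."""
    for _ in range(200):
        a = random_binary_mask(rng, (24, 24), p=0.35)
        b = random_binary_mask(rng, (24, 24), p=0.35)
        truth = random_binary_mask(rng, (24, 24), p=0.3)
        fused = fuse_predictions(a, b, FusionConfig(strategy="pixel_and"))
        fp = lambda m: confusion_counts(m, truth).fp  # noqa: E731
        assert fp(fused) <= min(fp(a), fp(b))
        spec = lambda m: specificity(confusion_counts(m, truth))  # noqa: E731
        assert spec(fused) >= max(spec(a), spec(b)) - 1e-12


def test_retention_is_labelling_order_invariant(rng):
    """Fusing (a, b) vs (b, a) gives the same mask — no order effects."""
    cfg = FusionConfig(strategy="component_overlap")
    for _ in range(50):
        a = random_binary_mask(rng, (20, 20), p=0.4)
        b = random_binary_mask(rng, (20, 20), p=0.4)
        assert np.array_equal(fuse_predictions(a, b, cfg),
                              fuse_predictions(b, a, cfg))


def test_postprocess_pipeline_end_to_end(disc_pair):
    truth = disc_pair.mask
    prob = truth.astype(float) * 0.9 + 0.05
    fused = postprocess_pipeline(prob, prob, 0.5,
                                 FusionConfig(min_component_size=10))
    assert np.array_equal(fused, truth)
    # a small spurious blob on one branch is cleaned before fusion
    noisy = prob.copy()
    noisy[:2, :2] = 0.95  # 4-px blob, below min size 10
    fused = postprocess_pipeline(noisy, prob, 0.5,
                                 FusionConfig(min_component_size=10))
    assert np.array_equal(fused, truth)
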