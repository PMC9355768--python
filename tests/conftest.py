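import numpy as np
import pytest

from lesionfuse.data import ImageMaskPair
from lesionfuse.models import ModelSpec
from lesionfuse.synthetic import SynthConfig, generate_pair


def tiny_spec(name: str, seed: int = 0) -> ModelSpec:
    """Desk-scale branch: width 8, depth 3 (shape contracts identical)."""
    return ModelSpec(name=name, base_width=8, max_width=64, depth=3, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_pair() -> ImageMaskPair:
    """A clean 128x128 disc lesion (exact circle, no hair, no noise)."""
    cfg = SynthConfig(size=128, border_irregularity=0.0, n_hairs=0,
                      noise_sigma=0.0, lesion_radius_range=(0.25, 0.25))
    return generate_pair(cfg, np.random.default_rng(0))


@pytest.fixture
def lesion_pair() -> ImageMaskPair:
    """A default irregular-border synthetic lesion with hair artifacts."""
    return generate_pair(SynthConfig(size=96), np.random.default_rng(7))


def random_binary_mask(rng: np.random.Generator, shape=(32, 32),
                       p: float = 0.5) -> np.ndarray:
    return (rng.uniform(size=shape) < p).astype(np.uint8)
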