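"""Architecture contracts: shapes, ranges, residual behaviour, init, I/O."""

import numpy as np
import pytest

from conftest import tiny_spec
from lesionfuse.losses import fusion_loss
from lesionfuse.models import (
    ModelSpec, build_model, build_residual_block, build_vnet2d,
    build_unet_resnet2d, init_weights_xavier, save_checkpoint, load_checkpoint,
)
from lesionfuse.nn import Tensor


def _checksum(model):
    return [p.data.sum() for p in model.parameters()]


@pytest.mark.parametrize("name", ["vnet2d", "unet_resnet2d"])
def test_forward_shape_and_range(name, rng):
    model = build_model(tiny_spec(name, seed=3))
    x = Tensor(rng.uniform(0, 1, (2, 1, 64, 64)))
    y = model.forward(x)
    assert y.shape == (2, 1, 64, 64)
    assert 0 < y.data.min() and y.data.max() < 1


@pytest.mark.parametrize("name", ["vnet2d", "unet_resnet2d"])
def test_fully_convolutional_any_divisible_size(name, rng):
    model = build_model(tiny_spec(name))
    y = model.forward(Tensor(rng.uniform(0, 1, (1, 1, 32, 48))))
    assert y.shape == (1, 1, 32, 48)
    with pytest.raises(ValueError, match="divisible"):
        model.forward(Tensor(rng.uniform(0, 1, (1, 1, 30, 30))))


def test_widths_follow_doubling_cap():
    spec = ModelSpec(name="vnet2d", base_width=32, max_width=512, depth=5)
    assert spec.widths == [32, 64, 128, 256, 512]
    deeper = ModelSpec(name="vnet2d", base_width=32, max_width=512, depth=6)
    assert deeper.widths[-1] == 512  # capped


def test_depth_validation():
    with pytest.raises(ValueError, match="depth"):
        ModelSpec(name="vnet2d", depth=1)
    with pytest.raises(ValueError):
        ModelSpec(name="nope")


def test_default_norm_per_architecture():
    assert ModelSpec(name="vnet2d").norm == "group"
    assert ModelSpec(name="unet_resnet2d").norm == "batch"


def test_build_guards_wrong_spec_name():
    with pytest.raises(ValueError):
        build_vnet2d(ModelSpec(name="unet_resnet2d"))
    with pytest.raises(ValueError):
        build_unet_resnet2d(ModelSpec(name="vnet2d"))


def test_residual_block_identity_shortcut(rng):
    block = build_residual_block(8, 8, norm="group")
    assert block.shortcut.__class__.__name__ == "Identity"
    proj = build_residual_block(8, 16, norm="batch")
    assert proj.shortcut.__class__.__name__ == "Conv2d"


def test_residual_block_zeroed_branch_passes_input(rng):
    """With zeroed conv weights the block reduces to its shortcut."""
    block = build_residual_block(4, 4, norm="group")
    for _, p in block.named_parameters():
        if p.data.ndim == 4:  # conv kernels only; keep norm gains at 1
            p.data[...] = 0.0
    x = rng.uniform(-1, 1, (2, 4, 8, 8))
    out = block(Tensor(x))
    assert np.allclose(out.data, x, atol=1e-12)


@pytest.mark.parametrize("name", ["vnet2d", "unet_resnet2d"])
def test_build_determinism(name):
    a = build_model(tiny_spec(name, seed=11))
    b = build_model(tiny_spec(name, seed=11))
    c = build_model(tiny_spec(name, seed=12))
    assert _checksum(a) == _checksum(b)
    assert _checksum(a) != _checksum(c)


def test_unet_bottleneck_spatial_size(rng):
    """Four poolings reduce 512 -> 32; verified at desk scale 64 -> 4."""
    spec = ModelSpec(name="unet_resnet2d", base_width=4, max_width=32, depth=5)
    model = build_model(spec)
    sizes = []
    x = Tensor(rng.uniform(0, 1, (1, 1, 64, 64)))
    h = x
    for level, block in enumerate(model.net.enc_blocks):
        h = block(h)
        if level < spec.depth - 1:
            h = model.net.downs[level](h)
            sizes.append(h.shape[2])
    assert sizes == [32, 16, 8, 4]  # 64 / 2**k, mirroring 512 -> 32


def test_xavier_statistics():
    spec = ModelSpec(name="vnet2d", base_width=32, max_width=128, depth=3,
                     seed=21)
    model = build_model(spec)
    init_weights_xavier(model, seed=42)
    for name, p in model.net.named_parameters():
        if p.data.ndim == 4 and p.data.size >= 10_000:
            shape = p.data.shape
            receptive = shape[2] * shape[3]
            fan_sum = (shape[0] + shape[1]) * receptive
            expected_var = 2.0 / fan_sum
            assert p.data.var() == pytest.approx(expected_var, rel=0.10)
        if name.endswith("bias"):
            assert np.all(p.data == 0.0)


def test_xavier_deterministic():
    spec = tiny_spec("unet_resnet2d")
    a = init_weights_xavier(build_model(spec), seed=5)
    b = init_weights_xavier(build_model(spec), seed=5)
    assert _checksum(a) == _checksum(b)


@pytest.mark.parametrize("name", ["vnet2d", "unet_resnet2d"])
def test_every_parameter_receives_gradient(name, rng):
    model = build_model(tiny_spec(name, seed=2))
    x = Tensor(rng.uniform(0, 1, (2, 1, 32, 32)))
    truth = Tensor((rng.uniform(size=(2, 1, 32, 32)) > 0.6).astype(float))
    loss = fusion_loss(model.forward(x), truth)
    loss.backward()
    for pname, p in model.net.named_parameters():
        assert p.grad is not None, f"no gradient reached {pname}"
        assert np.any(p.grad != 0), f"gradient is identically zero at {pname}"


def test_checkpoint_roundtrip(tmp_path, rng):
    model = build_model(tiny_spec("vnet2d", seed=8))
    x = rng.uniform(0, 1, (1, 32, 32))
    before = model.predict_probs(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.spec == model.spec
    assert np.allclose(restored.predict_probs(x), before)
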