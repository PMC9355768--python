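"""The two encoder-decoder segmentation branches.

V-Net2D: residual stages (1 convolution in the first stage, 2 in the second,
3 in deeper stages, each stage adding its input back), stride-2 2x2
convolutions for downsampling, group normalization, transposed-convolution
decoder with skip concatenation, sigmoid 1x1 head.

U-Net+ResNet2D: classic U-Net topology with every double convolution
replaced by a two-conv residual block, 2x2 max pooling, batch normalization,
transposed-convolution decoder with skip concatenation, sigmoid 1x1 head.

Channel widths double per level from ``base_width`` (32 at full scale) and
are capped at ``max_width`` (512).  Both networks are fully convolutional:
any input whose sides are divisible by ``2**(depth-1)`` maps to an output of
identical spatial size with values in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

__all__ = [
    "ModelSpec", "SegmentationModel", "ResidualBlock",
    "build_residual_block", "build_vnet2d", "build_unet_resnet2d",
    "build_model", "init_weights_xavier", "save_checkpoint", "load_checkpoint",
]

_NORMS = {"group", "batch"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one segmentation branch."""

    name: str = "vnet2d"
    in_channels: int = 1
    base_width: int = 32
    max_width: int = 512
    depth: int = 5
    norm: str | None = None  # default: group for vnet2d, batch for unet_resnet2d
    groups: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.name not in ("vnet2d", "unet_resnet2d"):
            raise ValueError(f"unknown architecture {self.name!r}")
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.norm is None:
            default = "group" if self.name == "vnet2d" else "batch"
            object.__setattr__(self, "norm", default)
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {_NORMS}")

    @property
    def widths(self) -> list[int]:
        """Encoder widths: base * 2**level, capped at max_width."""
        return [min(self.base_width * 2**level, self.max_width)
                for level in range(self.depth)]


def _make_norm(spec: ModelSpec, channels: int) -> nn.Module:
    if spec.norm == "group":
        groups = min(spec.groups, channels)
        while channels % groups:
            groups -= 1
        return nn.GroupNorm(groups, channels)
    return nn.BatchNorm2d(channels)


class ResidualBlock(nn.Module):
    """``n_convs`` x (3x3 conv + norm [+ ReLU]) plus a shortcut.

    The shortcut is the identity when input and output channels agree and a
    1x1 projection otherwise; no activation follows the addition, so a block
    whose conv weights are zero passes its (projected) input through.
    """

    def __init__(self, in_channels: int, out_channels: int, spec: ModelSpec,
                 n_convs: int = 2):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if n_convs < 1:
            raise ValueError("residual block needs at least one convolution")
        self.convs = []
        self.norms = []
        ch = in_channels
        for _ in range(n_convs):
            self.convs.append(nn.Conv2d(ch, out_channels, 3, padding=1))
            self.norms.append(_make_norm(spec, out_channels))
            ch = out_channels
        if in_channels == out_channels:
            self.shortcut = nn.Identity()
        else:
            self.shortcut = nn.Conv2d(in_channels, out_channels, 1)

    def forward(self, x):
        x = as_tensor(x)
        h = x
        last = len(self.convs) - 1
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            h = norm(conv(h))
            if i < last:
                h = h.relu()
        return h + self.shortcut(x)


def build_residual_block(in_channels: int, out_channels: int,
                         norm: str = "batch", groups: int = 8) -> ResidualBlock:
    """Standalone residual block with the given normalization."""
    spec = ModelSpec(name="vnet2d" if norm == "group" else "unet_resnet2d",
                     norm=norm, groups=groups)
    return ResidualBlock(in_channels, out_channels, spec)


class _ConvNormRelu(nn.Module):
    def __init__(self, in_channels, out_channels, spec, kernel=2, stride=2,
                 transpose=False):
        super().__init__()
        if transpose:
            self.conv = nn.ConvTranspose2d(in_channels, out_channels, kernel, stride)
        else:
            self.conv = nn.Conv2d(in_channels, out_channels, kernel, stride)
        self.norm = _make_norm(spec, out_channels)

    def forward(self, x):
        return self.norm(self.conv(x)).relu()


class _EncoderDecoderNet(nn.Module):
    """Shared U-shaped skeleton; the spec decides blocks and downsampling."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        widths = spec.widths
        vnet = spec.name == "vnet2d"

        def stage_convs(level: int) -> int:
            # V-Net: 1 conv in stage 1, 2 in stage 2, 3 deeper; U-Net: always 2
            return min(level + 1, 3) if vnet else 2

        self.enc_blocks = []
        for level, width in enumerate(widths):
            if level == 0:
                ch = spec.in_channels
            elif vnet:
                ch = width  # strided down-conv already set the channel count
            else:
                ch = widths[level - 1]  # max pooling keeps channels
            self.enc_blocks.append(
                ResidualBlock(ch, width, spec, n_convs=stage_convs(level)))

        # V-Net downsamples with strided 2x2 convs (doubling channels there);
        # U-Net+ResNet2D max-pools, and channel growth happens in the next block.
        self.downs = []
        for level in range(spec.depth - 1):
            if vnet:
                self.downs.append(
                    _ConvNormRelu(widths[level], widths[level + 1], spec))
            else:
                self.downs.append(nn.MaxPool2d(2))

        self.ups = []
        self.dec_blocks = []
        for level in range(spec.depth - 2, -1, -1):
            self.ups.append(_ConvNormRelu(
                widths[level + 1], widths[level], spec, transpose=True))
            self.dec_blocks.append(ResidualBlock(
                2 * widths[level], widths[level], spec,
                n_convs=stage_convs(level)))

        self.head = nn.Conv2d(widths[0], 1, 1)

    def forward(self, x):
        x = as_tensor(x)
        h, w = x.shape[2], x.shape[3]
        factor = 2 ** (self.spec.depth - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"input spatial size ({h},{w}) must be divisible by {factor} "
                f"for depth {self.spec.depth}; pad the image to a multiple")
        skips = []
        for level, block in enumerate(self.enc_blocks):
            x = block(x)
            if level < self.spec.depth - 1:
                skips.append(x)
                x = self.downs[level](x)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up(x)
            x = nn.concatenate([x, skip], axis=1)
            x = block(x)
        return self.head(x).sigmoid()


@dataclass
class SegmentationModel:
    """A built branch: spec + network, with batch-array prediction helpers."""

    spec: ModelSpec
    net: nn.Module

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    def predict_probs(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Probability maps for (N, H, W) or (N, 1, H, W) images in [0, 1]."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[:, None]
        self.net.eval()
        out = []
        for start in range(0, len(images), batch_size):
            batch = Tensor(images[start:start + batch_size])
            out.append(self.net(batch).data[:, 0])
        return np.concatenate(out, axis=0)

    def parameters(self):
        return self.net.parameters()


def init_weights_xavier(model: SegmentationModel, seed: int) -> SegmentationModel:
    """Glorot-uniform re-initialization of all conv weights; zero biases."""
    nn.xavier_init_(model.net, seed)
    return model


def build_vnet2d(spec: ModelSpec) -> SegmentationModel:
    if spec.name != "vnet2d":
        raise ValueError(f"spec.name is {spec.name!r}, expected 'vnet2d'")
    model = SegmentationModel(spec=spec, net=_EncoderDecoderNet(spec))
    return init_weights_xavier(model, spec.seed)


def build_unet_resnet2d(spec: ModelSpec) -> SegmentationModel:
    if spec.name != "unet_resnet2d":
        raise ValueError(f"spec.name is {spec.name!r}, expected 'unet_resnet2d'")
    model = SegmentationModel(spec=spec, net=_EncoderDecoderNet(spec))
    return init_weights_xavier(model, spec.seed)


def build_model(spec: ModelSpec) -> SegmentationModel:
    return build_vnet2d(spec) if spec.name == "vnet2d" else build_unet_resnet2d(spec)


def save_checkpoint(model: SegmentationModel, path: Path | str) -> None:
    """Serialize parameters plus the embedded spec (rebuildable from file)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.net.state_dict()
    np.savez(path, __spec__=json.dumps(asdict(model.spec)), **state)


def load_checkpoint(path: Path | str) -> SegmentationModel:
    with np.load(Path(path), allow_pickle=False) as archive:
        spec = ModelSpec(**json.loads(str(archive["__spec__"])))
        state = {k: archive[k] for k in archive.files if k != "__spec__"}
    model = build_model(spec)
    model.net.load_state_dict(state)
    return model
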