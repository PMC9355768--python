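"""Neural-network modules built on the autodiff engine.

Mirrors the familiar Module/Parameter API at the scale this package needs:
convolutions, transposed convolutions, max pooling, group and batch
normalization, and a Sequential container.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, as_tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "ConvTranspose2d",
    "MaxPool2d", "GroupNorm", "BatchNorm2d", "ReLU", "Sigmoid", "Identity",
]


class Parameter(Tensor):
    """A tensor registered as learnable state."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # persistent non-learnable state (running BN statistics)
    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.array(value, dtype=np.float64)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        k = kernel_size
        # placeholder init; networks re-initialize with the Xavier scheme
        scale = 1.0 / np.sqrt(in_channels * k * k)
        self.weight = Parameter(np.random.default_rng(0).uniform(
            -scale, scale, size=(out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 stride: int = 2, bias: bool = True):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        k = kernel_size
        scale = 1.0 / np.sqrt(in_channels * k * k)
        self.weight = Parameter(np.random.default_rng(0).uniform(
            -scale, scale, size=(in_channels, out_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x):
        return F.max_pool2d(x, self.size)


class GroupNorm(Module):
    """Normalize over channel groups; batch-size independent."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError(
                f"channels ({num_channels}) not divisible by groups ({num_groups})")
        self.num_groups = num_groups
        self.eps = eps
        self.gamma = Parameter(np.ones((1, num_channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_channels, 1, 1)))

    def forward(self, x):
        x = as_tensor(x)
        n, c, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        centred = xg - mu
        var = (centred * centred).mean(axis=2, keepdims=True)
        xhat = (centred / (var + self.eps).sqrt()).reshape(n, c, h, w)
        return xhat * self.gamma + self.beta


class BatchNorm2d(Module):
    """Per-channel normalization over the batch, with running statistics."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, num_channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_channels, 1, 1)))
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x):
        x = as_tensor(x)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = centred / (var + self.eps).sqrt()
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var[None, :, None, None] + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return as_tensor(x).relu()


class Sigmoid(Module):
    def forward(self, x):
        return as_tensor(x).sigmoid()


class Identity(Module):
    def forward(self, x):
        return as_tensor(x)
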