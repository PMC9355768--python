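"""Weight initialization (Glorot/Xavier uniform, zero biases)."""

from __future__ import annotations

import numpy as np

from .layers import Module

__all__ = ["xavier_init_"]


def _fans(shape: tuple[int, ...]) -> tuple[int, int]:
    if len(shape) == 2:  # linear: (out, in)
        return shape[1], shape[0]
    # conv kernels: conv2d (O, C, kh, kw); conv_transpose2d (C, O, kh, kw).
    # Receptive-field size multiplies both fans either way.
    receptive = int(np.prod(shape[2:]))
    return shape[1] * receptive, shape[0] * receptive


def xavier_init_(model: Module, seed: int) -> Module:
    """Re-draw every conv/linear weight ``W ~ U(-a, a)``, ``a = sqrt(6/(fan_in+fan_out))``.

    Gives Var[W] = 2/(fan_in+fan_out). Biases are zeroed; normalization scale
    and shift parameters keep their (1, 0) defaults. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    for name, p in model.named_parameters():
        if p.data.ndim >= 2:
            fan_in, fan_out = _fans(p.data.shape)
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            p.data = rng.uniform(-limit, limit, size=p.data.shape)
        elif name.endswith("bias"):
            p.data = np.zeros_like(p.data)
    return model
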