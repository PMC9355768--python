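"""Training loop: Adam on the fused (or single) loss, with validation tracking.

Follows the published configuration — Xavier-initialized weights, ReLU
activations, Adam at learning rate 1e-3 with batches of 4 — scaled to a
configurable number of optimizer steps.  A fraction of the training pairs is
held out for validation; the returned model carries the parameters of the
best-validation-Dice checkpoint, and the full loss/metric history is
recorded for learning-curve plots.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import DatasetSplit, ImageMaskPair
from .losses import TverskyParams, dice_loss, focal_tversky_loss, fusion_loss
from .metrics import confusion_counts, dice, accuracy
from .models import SegmentationModel
from .nn import Tensor, Adam

__all__ = ["TrainConfig", "TrainHistory", "train", "predict", "pairs_to_arrays"]

_LOSSES = ("dice", "ftl", "fusion")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 4
    max_steps: int = 200
    val_fraction: float = 0.2
    loss: str = "fusion"
    tversky: TverskyParams = field(default_factory=TverskyParams)
    seed: int = 0
    eval_every: int = 20
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")


@dataclass
class TrainHistory:
    """Per-step training loss and periodic validation records."""

    steps: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_step: int = -1
    best_val_dice: float = -1.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TrainHistory":
        return cls(**json.loads(text))

    def save_csv(self, path: Path | str) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "train_loss"])
            writer.writerows(zip(self.steps, self.train_loss))
        val_path = path.with_name(path.stem + "_val" + path.suffix)
        with open(val_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "val_loss", "val_dice", "val_accuracy"])
            writer.writerows(zip(self.val_steps, self.val_loss,
                                 self.val_dice, self.val_accuracy))


def pairs_to_arrays(pairs: list[ImageMaskPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into (N,1,H,W) image and mask arrays; images scaled to [0,1]."""
    images = np.stack([np.asarray(p.image, dtype=np.float64) / 255.0
                       for p in pairs])[:, None]
    masks = np.stack([p.mask.astype(np.float64) for p in pairs])[:, None]
    return images, masks


def _loss_fn(cfg: TrainConfig):
    if cfg.loss == "dice":
        return lambda p, t: dice_loss(p, t)
    if cfg.loss == "ftl":
        return lambda p, t: focal_tversky_loss(p, t, cfg.tversky)
    return lambda p, t: fusion_loss(p, t, cfg.tversky)


def _validate(model: SegmentationModel, images, masks, cfg, loss_fn):
    probs = model.predict_probs(images[:, 0], batch_size=cfg.batch_size)
    v_loss = float(loss_fn(Tensor(probs), Tensor(masks[:, 0])).item())
    dices, accs = [], []
    for i in range(len(images)):
        counts = confusion_counts(probs[i] > cfg.threshold, masks[i, 0] > 0.5)
        dices.append(dice(counts))
        accs.append(accuracy(counts))
    return v_loss, float(np.mean(dices)), float(np.mean(accs))


def train(model: SegmentationModel, data: DatasetSplit | list[ImageMaskPair],
          cfg: TrainConfig = TrainConfig()) -> tuple[SegmentationModel, TrainHistory]:
    """Optimize ``model`` and return it with best-validation parameters loaded."""
    pairs = data.train if isinstance(data, DatasetSplit) else list(data)
    if not pairs:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, round(cfg.val_fraction * len(pairs)))
    if n_val >= len(pairs):
        raise ValueError("validation split leaves no training pairs")
    order = rng.permutation(len(pairs))
    val_pairs = [pairs[i] for i in order[:n_val]]
    train_pairs = [pairs[i] for i in order[n_val:]]

    x_train, y_train = pairs_to_arrays(train_pairs)
    x_val, y_val = pairs_to_arrays(val_pairs)

    loss_fn = _loss_fn(cfg)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_state = model.net.state_dict()

    n = len(train_pairs)
    epoch_order = rng.permutation(n)
    cursor = 0
    for step in range(1, cfg.max_steps + 1):
        if cursor + cfg.batch_size > n:
            epoch_order = rng.permutation(n)
            cursor = 0
        idx = epoch_order[cursor:cursor + cfg.batch_size]
        cursor += cfg.batch_size

        model.net.train()
        batch_loss = loss_fn(model.forward(Tensor(x_train[idx])),
                             Tensor(y_train[idx]))
        value = float(batch_loss.item())
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite training loss ({value}) at step {step}; "
                "lower the learning rate or check the input scaling")
        optimizer.zero_grad()
        batch_loss.backward()
        optimizer.step()
        history.steps.append(step)
        history.train_loss.append(value)

        if step % cfg.eval_every == 0 or step == cfg.max_steps:
            v_loss, v_dice, v_acc = _validate(model, x_val, y_val, cfg, loss_fn)
            history.val_steps.append(step)
            history.val_loss.append(v_loss)
            history.val_dice.append(v_dice)
            history.val_accuracy.append(v_acc)
            if v_dice > history.best_val_dice:
                history.best_val_dice = v_dice
                history.best_step = step
                best_state = model.net.state_dict()

    model.net.load_state_dict(best_state)
    model.net.eval()
    return model, history


def predict(model: SegmentationModel, images: np.ndarray,
            threshold: float = 0.5, batch_size: int = 4) -> np.ndarray:
    """Thresholded binary masks for a batch of [0,1]-scaled images."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    factor = 2 ** (model.spec.depth - 1)
    h, w = images.shape[-2], images.shape[-1]
    if h % factor or w % factor:
        raise ValueError(
            f"image size ({h},{w}) incompatible with model depth "
            f"{model.spec.depth}; pad to a multiple of {factor}")
    probs = model.predict_probs(images, batch_size=batch_size)
    return (probs > threshold).astype(np.uint8)
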