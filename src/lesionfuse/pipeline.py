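"""End-to-end orchestration: data -> preprocess -> augment -> train two
branches -> predict -> clean + fuse -> evaluation report.

One top-level seed fans out deterministically to the split, augmentation,
model initialization, and batching, so a run is reproducible from its
configuration alone.  The report carries the five overlap metrics for each
branch and for the fused prediction, in per-image-mean and pooled-count
variants.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, augment_dataset
from .data import DatasetSplit, ImageMaskPair, save_mask, split_dataset
from .fusion import FusionConfig, postprocess_pipeline, remove_small_components
from .metrics import aggregate_reports
from .models import ModelSpec, build_model, save_checkpoint
from .preprocess import PreprocessConfig, preprocess_pair
from .synthetic import SynthConfig, generate_dataset
from .training import TrainConfig, pairs_to_arrays, train

__all__ = ["PipelineConfig", "run_pipeline", "report_to_markdown",
           "synthetic_pipeline_config"]

logger = logging.getLogger("lesionfuse.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig | None = None  # None disables augmentation
    model_a: ModelSpec = field(default_factory=lambda: ModelSpec(name="vnet2d"))
    model_b: ModelSpec = field(
        default_factory=lambda: ModelSpec(name="unet_resnet2d"))
    train: TrainConfig = field(default_factory=TrainConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    test_fraction: float = 0.2
    output_dir: Path | str | None = None
    seed: int = 0


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(pairs: list[ImageMaskPair],
                 cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Run the full segmentation pipeline on ``pairs``; return the report."""
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(6) % (2**31)
    timings = {}
    stage = "split"
    try:
        t0 = _stage(stage)
        split = split_dataset(pairs, cfg.test_fraction, int(seeds[0]))
        timings[stage] = time.time() - t0

        stage = "preprocess"
        t0 = _stage(stage)
        train_pairs = [preprocess_pair(p, cfg.preprocess) for p in split.train]
        test_pairs = [preprocess_pair(p, cfg.preprocess) for p in split.test]
        timings[stage] = time.time() - t0

        stage = "augment"
        t0 = _stage(stage)
        if cfg.augment is not None:
            train_pairs = augment_dataset(
                train_pairs, replace(cfg.augment, seed=int(seeds[1])))
        timings[stage] = time.time() - t0

        models, histories = {}, {}
        for key, spec, seed_init, seed_train in (
                ("branch_a", cfg.model_a, seeds[2], seeds[3]),
                ("branch_b", cfg.model_b, seeds[4], seeds[5])):
            stage = f"train:{spec.name}"
            t0 = _stage(stage)
            model = build_model(replace(spec, seed=int(seed_init)))
            model, history = train(
                model,
                DatasetSplit(train=train_pairs, test=test_pairs, seed=cfg.seed),
                replace(cfg.train, seed=int(seed_train)))
            models[key], histories[key] = model, history
            timings[stage] = time.time() - t0
            if out_dir:
                save_checkpoint(model, out_dir / f"{spec.name}.npz")
                history.save_csv(out_dir / f"{spec.name}_history.csv")

        stage = "predict+fuse"
        t0 = _stage(stage)
        x_test, _ = pairs_to_arrays(test_pairs)
        probs = {key: models[key].predict_probs(x_test[:, 0])
                 for key in models}
        branch_masks = {
            key: np.stack([
                remove_small_components(
                    (pr > cfg.train.threshold).astype(np.uint8),
                    cfg.fusion.min_component_size, cfg.fusion.connectivity)
                for pr in probs[key]])
            for key in probs
        }
        fused = np.stack([
            postprocess_pipeline(probs["branch_a"][i], probs["branch_b"][i],
                                 cfg.train.threshold, cfg.fusion)
            for i in range(len(test_pairs))
        ])
        timings[stage] = time.time() - t0

        stage = "evaluate"
        truths = [p.mask for p in test_pairs]
        rows = {}
        for key, label in (("branch_a", cfg.model_a.name),
                           ("branch_b", cfg.model_b.name)):
            rows[label] = aggregate_reports(zip(branch_masks[key], truths))
        rows["fused"] = aggregate_reports(zip(fused, truths))

        report = {
            "rows": rows,
            "n_train": len(train_pairs),
            "n_test": len(test_pairs),
            "seed": cfg.seed,
            "fusion_strategy": cfg.fusion.strategy,
            "best_val_dice": {k: histories[k].best_val_dice for k in histories},
            "timings_s": {k: round(v, 2) for k, v in timings.items()},
        }
        if out_dir:
            masks_dir = out_dir / "fused_masks"
            for pair, mask in zip(test_pairs, fused):
                save_mask(mask, masks_dir / f"{pair.id}_segmentation.png")
            (out_dir / "report.json").write_text(json.dumps(report, indent=2))
            (out_dir / "report.md").write_text(report_to_markdown(report))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def report_to_markdown(report: dict, variant: str = "per_image") -> str:
    """Render the report rows as a metrics table."""
    metrics = ["dice", "jaccard", "accuracy", "sensitivity", "specificity"]
    lines = ["| model | " + " | ".join(m.capitalize() for m in metrics) + " |",
             "|" + "---|" * (len(metrics) + 1)]
    for label, row in report["rows"].items():
        values = row[variant]
        lines.append("| " + label + " | " +
                     " | ".join(f"{values[m]:.4f}" for m in metrics) + " |")
    return "\n".join(lines) + "\n"


def synthetic_pipeline_config(n_pairs: int = 200, size: int = 96,
                              seed: int = 0, **synth_kwargs) -> tuple[
                                  list[ImageMaskPair], PipelineConfig]:
    """Convenience: a desk-scale synthetic dataset plus a matching config.

    Tiny branches (width 8, depth 3) on ``size`` x ``size`` synthetic pairs in
    the easy high-contrast regime by default.
    """
    synth = SynthConfig(size=size, contrast=synth_kwargs.pop("contrast", 0.8),
                        noise_sigma=synth_kwargs.pop("noise_sigma", 4.0),
                        seed=seed, **synth_kwargs)
    pairs = generate_dataset(n_pairs, synth, seed=seed)
    cfg = PipelineConfig(
        preprocess=PreprocessConfig(target_size=(size, size)),
        augment=None,
        model_a=ModelSpec(name="vnet2d", base_width=8, max_width=64, depth=3),
        model_b=ModelSpec(name="unet_resnet2d", base_width=8, max_width=64,
                          depth=3),
        train=TrainConfig(max_steps=300),
        fusion=FusionConfig(min_component_size=16),
        seed=seed,
    )
    return pairs, cfg
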