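# lesionfuse

Fused encoder–decoder segmentation of skin lesions in dermoscopy images.

Automatic lesion segmentation is the first step of computer-aided melanoma
screening, and it is hard for well-known reasons: hair and other artifacts
cross the lesion boundary, and the contrast between lesioned and normal
skin can be very low. `lesionfuse` implements a fusion approach to this
problem for researchers who want a fully tested, CPU-runnable reference:
two complementary convolutional branches are trained independently and
their predictions are merged by overlap-based post-processing.

The pieces:

* **V-Net2D** — residual encoder stages (1, 2, then 3 convolutions per
  stage, each stage adding its input back), strided 2×2 down-convolutions,
  group normalization, transposed-convolution decoder with skip
  concatenation, sigmoid 1×1 head.
* **U-Net+ResNet2D** — U-Net topology with every double convolution
  replaced by a residual block, 2×2 max pooling, batch normalization.
* **Fused loss** — both branches minimize `DL + FTL`, where
  `DL = 1 − softDice`, `FTL = (1 − TI)^γ`, and
  `TI = TP / (TP + α·FN + β·FP)` is the soft Tversky index
  (α = 0.7, β = 0.3, γ = 0.75). The Tversky asymmetry biases toward
  recall; the focal exponent concentrates gradient on hard examples;
  the Dice term drives global overlap.
* **Prediction fusion** — each branch's thresholded mask is cleaned of
  small connected components, then components confirmed by the other
  branch (overlap fraction ≥ 0.5) are kept; a conservative pixel-wise
  intersection rule is also provided.
* **Recipe** — percentile contrast stretching, unsharp-mask sharpening,
  resize to a uniform input, RGB→luma; training-set augmentation by flips,
  rotation, grid distortion, elastic warps, and lesion-boundary crops.
* **Synthetic data** — a generator of dermoscopy-like images (skin-toned
  background, irregular-border lesion of controllable contrast, hair-like
  artifacts) so the whole pipeline runs and is tested without any
  downloads.

Because no deep-learning framework is required, the networks run on a
small, fully tested reverse-mode autodiff engine over numpy that ships
inside the package (`lesionfuse.nn`).

## Worked example

```python
import numpy as np
from lesionfuse import (
    SynthConfig, generate_dataset, ModelSpec, build_model,
    TrainConfig, train, predict, postprocess_pipeline, FusionConfig,
    confusion_counts, dice,
)

# 30 synthetic dermoscopy-like pairs, 64x64, high contrast
pairs = generate_dataset(30, SynthConfig(size=64, contrast=0.8,
                                         noise_sigma=4.0), seed=11)
train_pairs, test_pairs = pairs[:24], pairs[24:]

spec = dict(base_width=8, max_width=64, depth=3)   # desk-scale widths
cfg = TrainConfig(max_steps=60, eval_every=30)
vnet, _ = train(build_model(ModelSpec(name="vnet2d", **spec)),
                train_pairs, cfg)
unet, _ = train(build_model(ModelSpec(name="unet_resnet2d", **spec)),
                train_pairs, cfg)

images = np.stack([p.image / 255.0 for p in test_pairs])
fused = [postprocess_pipeline(vnet.predict_probs(images)[i],
                              unet.predict_probs(images)[i],
                              0.5, FusionConfig(min_component_size=8))
         for i in range(len(test_pairs))]
scores = [dice(confusion_counts(m, p.mask))
          for m, p in zip(fused, test_pairs)]
print(f"fused test dice: {np.mean(scores):.3f}")
```

```
fused test dice: 0.951
```

The fused mask agrees with the synthetic ground truth on ~95 % of lesion
overlap after only 60 optimization steps per branch — the easy-contrast regime
is learnable by the tiny desk-scale branches in seconds per step on a CPU.
(Accuracy figures at clinical scale require the real ISIC 2018 dataset and
GPU-scale training, which are outside this package's scope.)

The same flow is scriptable from the shell:

```bash
lesionfuse synth --n 200 --out data/ --seed 7
lesionfuse preprocess --in data/ --out prep/
lesionfuse train --arch vnet2d --data prep/ --out ckpt/ --loss fusion
lesionfuse evaluate --pred preds/ --truth truth/ --report report.json
lesionfuse fuse --pred-a preds_a/ --pred-b preds_b/ --out fused/
lesionfuse run --config pipeline.yaml
```

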