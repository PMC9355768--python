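# Methods

## Problem and approach

`lesionfuse` segments skin lesions in dermoscopy images by fusing two
complementary encoder–decoder convolutional networks and post-processing
their agreement. The pipeline has five stages:

1. **Enhancement.** Percentile-based piecewise-linear contrast stretching
   (monotone, mapping the low percentile to 0 and the high percentile to
   255), unsharp-mask sharpening, resizing to a uniform network input size,
   and RGB→luma conversion (the networks consume one channel).
2. **Augmentation** (training only). Horizontal/vertical flips, random
   rotation, grid distortion, elastic deformation, and boundary crops
   centred on lesion-edge pixels; every transform applies one geometric map
   to image (bilinear) and mask (nearest neighbour).
3. **Two branches.** *V-Net2D*: residual stages with 1/2/3 convolutions in
   stages 1/2/3+, strided 2×2 down-convolutions, group normalization.
   *U-Net+ResNet2D*: U-Net topology with double convolutions replaced by
   two-conv residual blocks, 2×2 max pooling, batch normalization. Both use
   3×3 kernels, ReLU, transposed-convolution decoders with skip
   concatenation, and a sigmoid 1×1 head; channel widths double per level
   from `base_width` up to `max_width` (32→512 at full scale).
4. **Training.** Each branch minimizes the fused loss
   `L = DL + FTL` where `DL = 1 − softDice` and `FTL = (1 − TI)^γ` with the
   Tversky index `TI = TP/(TP + αFN + βFP)` computed on soft predictions.
   Defaults α = 0.7, β = 0.3 (penalizing missed lesion pixels harder than
   false alarms, biasing toward recall) and γ = 0.75 (amplifying gradients
   on poorly segmented examples). Optimization is Adam (β₁ = 0.9,
   β₂ = 0.999) at learning rate 1e-3 with batches of 4; weights are
   Glorot-uniform initialized with zero biases; the checkpoint with the
   best validation Dice is kept.
5. **Fusion post-processing.** Each branch's thresholded prediction is
   cleaned of connected components below a minimum size, then combined.
   `component_overlap` (default) keeps a component of either mask iff the
   fraction of its pixels confirmed by the other mask reaches the overlap
   threshold (0.5); `pixel_and` is the conservative intersection, under
   which the fused mask provably has no more false positives than either
   branch.

## Why a built-in autodiff engine

The networks, losses, and training loop run on a small reverse-mode
automatic-differentiation engine over numpy (`lesionfuse.nn`): a `Tensor`
with backpropagation through broadcasted arithmetic, reductions,
nonlinearities, im2col convolution, transposed convolution, max pooling,
and group/batch normalization, plus Adam and Glorot initialization. Writing
the engine in-package keeps the whole method self-contained and makes every
gradient testable against finite differences (the test suite checks each
primitive and each loss to 1e-4 relative or better). Everything is double
precision; model sizes are chosen so CPU execution stays practical.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α, β | 0.7, 0.3 | Tversky weights on FN and FP (unitless) |
| γ | 0.75 | focal exponent of the FTL (unitless, > 0) |
| smoothing ε | 1e-6 | numerator/denominator guard in soft ratios |
| learning rate | 1e-3 | Adam step size |
| batch size | 4 | images per optimization step |
| stretch percentiles | (2, 98) | robust contrast-stretch breakpoints |
| sharpen amount, σ | 10, 1 px | unsharp-mask gain and blur width |
| input size | 512×512 (tests: 64–96) | uniform network input |
| prediction threshold | 0.5 | sigmoid probability cut |
| min component size | 64 px at 512² (16 at 96²) | blob-cleanup floor |
| overlap threshold | 0.5 | component-retention fraction |
| connectivity | 8 | component adjacency (4 also supported) |
| GN groups | 8 | divides all widths from 32 up |

`FTL = (1−TI)^γ` is the implemented reading (γ = 1 recovers the plain
Tversky loss, which the equivalence test pins down); the alternative
`1 − TI^γ` is available via `complement_power=False`.

Epoch-scale training counts are expressed as optimizer steps (`max_steps`);
at full scale practitioners run 10⁵ steps, while the tests and the
acceptance script use hundreds, which suffices for the easy synthetic
regime below.

## Synthetic data: what it does and does not emulate

The generator produces a skin-toned background with Gaussian sensor noise,
one star-convex lesion per image darker than the skin by a configurable
contrast, an irregular border (radius r(θ) = r₀(1 + a·f(θ)) with f a
smooth unit-peak harmonic mixture, a the irregularity amplitude), and dark
anti-aliased Bézier hair strokes drawn over the image but excluded from the
mask. Star-convexity guarantees a single connected component and a known
analytic area (a clean disc's pixel count matches πr₀² within 2%), which
the geometry tests rely on.

It does **not** emulate: colour constancy shifts, vignetting, gel bubbles
and ruler markings, multi-lobed or multi-focal lesions, regression
structures, or realistic lesion texture. Passing tests therefore
demonstrate that the implementation is correct and that the method behaves
as designed on controllable imagery — not that it reaches any particular
accuracy on real dermoscopy data, which requires the full-scale dataset and
training budget.

Difficulty is a two-knob dial (contrast, noise): Otsu thresholding reaches
Dice > 0.9 at contrast 0.8 / no noise and < 0.6 at contrast 0.1 /
σ = 25, fixing an "easy" and a "hard" regime for training tests.

## Numerical choices and degenerate inputs

* Overlap metrics define the empty-vs-empty case as 1 (perfect agreement on
  absence); the ε-smoothed soft losses handle it without special cases.
* The gradient of `x^γ` (γ < 1) at x = 0 is unbounded; the engine returns a
  zero subgradient there, which occurs only at an exact optimum of the FTL.
* Masks are binarized at load with threshold 128 on 8-bit values, so
  lossy-compressed masks come out clean; nearest-neighbour resampling keeps
  them binary through every geometric transform.
* A constant image cannot be contrast-stretched and passes through with a
  warning; sharpening with amount 0 is the exact identity.
* Component retention in `component_overlap` is symmetric in the two masks
  and independent of labelling order.
* Both networks reject input sizes not divisible by 2^(depth−1) with a
  message suggesting padding, rather than silently mis-shaping the decoder.
* Training aborts with the step index on a non-finite loss.
* The top-level pipeline seed fans out to split/augmentation/initialization/
  batching seeds through `numpy.random.SeedSequence`, so one integer fully
  determines a run.

## Desk-scale problem sizes

Tests and the acceptance script use width-8 depth-3 branches (the shape
contracts are width-independent), 64×64 inputs for overfit checks (8 pairs,
200 steps), and a 200-pair 96×96 dataset (160 train / 40 test, 300 steps
per branch) for the end-to-end run. These sizes were chosen as the smallest
at which every pipeline property (training convergence, fusion behaviour,
reporting) is still exercised meaningfully.

## Known limitations

* CPU-only, double precision: full-scale (512×512, width-32 depth-5,
  10⁵ steps) training is out of reach of this engine; the package targets
  method correctness and desk-scale experimentation.
* Batch normalization statistics with batches of 4 are noisy; group
  normalization (the V-Net2D default) is the batch-size-robust choice.
* The component-overlap fusion rule is one concrete reading of
  "keep the most-overlapping regions"; the intersection rule is provided as
  the conservative alternative, and probability-level ensembling is
  deliberately out of scope.
* Augmentation magnitudes (rotation ±30°, elastic α = 30 / σ = 4, grid 4 /
  magnitude 8, boundary scale 0.8–1.2, each transform drawn with
  probability 0.5) are mild standard defaults, all configurable; no claim
  of optimality is made.
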