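# Methods

`hemafuse` implements a fine-grained single-cell image classifier for stained
blood-cell micrographs, built from four pieces: a class-token-free vision
transformer (ViT) encoder, squeeze-and-excitation (SE) fusion of all encoder
layers, a dynamic-margin sub-center angular-margin (ArcFace-family) loss, and
optional masked-autoencoder (MAE) self-supervised pre-training. Everything
runs on a vectorized numpy autodiff engine written for this package, so no
deep-learning framework is required.

## Model

**Backbone.** Images are resized to `image_size`, cut into
`patch_size x patch_size` RGB patches, linearly embedded into `dim`-vectors
and passed through `depth` pre-norm transformer blocks (multi-head
self-attention + 2-layer GELU MLP, residual connections, LayerNorm before
each sub-block, one final LayerNorm). The full-size preset is ViT-base/16:
224-pixel input, 16-pixel patches, 12 layers, width 768, 12 heads, MLP ratio
4.

**Positions.** Two modes. `"sincos"`: fixed 2-D sine-cosine encodings (half
the channels per axis, geometric frequency ladder), always used during MAE
pre-training. `"learned"`: a trainable `(num_tokens, dim)` table, the default
for the classifier presets — this is the variant whose trainable-parameter
count matches the reference accounting for both the 197-token baseline and
the 196-token fusion model. The two modes are interchangeable in every code
path; transfer between a sincos MAE and a learned-position classifier simply
leaves the table freshly initialized.

**Layer fusion.** The classifier keeps the output of *every* encoder block
(the final block after the last LayerNorm), mean-pools each over the token
axis into an `L x dim` stack, and gates the `L` layers with an SE bottleneck:
squeeze = mean over the feature axis, excitation = `L -> max(1, L/4) -> L`
MLP with ReLU and a sigmoid. The gated stack is summed over the layer axis
into a single `dim` feature. The second excitation map is zero-initialized so
every gate starts at exactly 0.5 — an even blend of all depths. Mean-pooling
before the gate is one of two defensible readings of layer "splicing"; it is
the minimal one consistent with a class-token-free encoder producing a
`dim`-sized feature, and it is the one implemented.

There is no class token in the fusion model (196 tokens at the base preset);
the vanilla baseline keeps it (197 tokens) and reads out the class token
through a linear head.

## Loss

Each class `c` owns `K` prototype vectors (sub-centers, default `K = 3`).
For embedding `x` the class score is the maximum cosine over the class's
sub-centers (all vectors L2-normalized; cosines clamped to
`[-1+1e-7, 1-1e-7]`; exact ties in the max resolve to the lowest sub-center
index). Training minimizes the additive-angular-margin softmax

    L = -log exp(s cos(theta_y + m_y)) /
             (exp(s cos(theta_y + m_y)) + sum_{j!=y} exp(s cos(theta_j)))

with scale `s = 64`. `cos(theta + m)` is computed through the angle-addition
identity (`cos t cos m - sin t sin m`), never an arccos round trip. The
margin is applied unconditionally (no "easy margin" branch).

**Dynamic margins.** Per-class margins come from the training-split class
counts: `m_c = (a - b) * n_c**lam + b` with `a = 0.5`, `b = 0.05`,
`lam = -0.5`. A singleton class gets the full margin `a`; abundant classes
decay as `1/sqrt(n_c)` toward the floor `b`. Rare classes are intrinsically
harder, and a larger margin demands tighter angular clustering exactly where
data is scarce. (The exponent is applied as written; a positive `lam` would
invert the intended monotonicity and is rejected by the bound/monotonicity
invariants in the test suite.) Margins are computed once per training run.

**Embedding centering.** The fused embedding of every image shares a large
common component (at toy scale the mean pairwise cosine between raw
embeddings exceeds 0.99, random or pre-trained weights alike). An angular
loss cannot see differences hiding behind a shared direction, so the head
centers embeddings before the cosine product: batch mean during training,
a running mean (momentum 0.9, persisted in checkpoints) at inference — the
standard embedding-normalization block of angular-margin heads. Single-sample
batches fall back to the running mean, whose subtraction of a sample's own
mean would otherwise annihilate it. The loss operation itself
(`SubcenterArcFace.loss`) is the pure formula above; centering lives upstream
in the classifier.

Loss ablation switches: `ce` (linear head + softmax cross-entropy),
`arcface` (K=1, fixed margin `a`), `subcenter` (K=3, fixed margin),
`dynamic-subcenter` (K=3, count-derived margins — the full method). Only the
head/objective changes; the backbone is identical.

## MAE pre-training

75% of patches are masked uniformly at random (`round(0.75 * N)`, exactly
147 of 196 at the base grid). The encoder — identical architecture to the
classifier backbone, without a class token, with sincos positions — sees only
visible patches plus their positions. A deliberately light decoder (default
8 blocks of width 512 at base scale; 1 block of width 32 in toy configs)
receives the encoded visible tokens re-interleaved with a shared learned mask
token, adds decoder positions, and linearly regresses all `patch_size**2 * 3`
pixel values per patch. The MSE loss covers masked patches only; the gradient
at visible positions is identically zero. Reconstruction targets are raw
(standardized-image) pixel values by default; per-patch-normalized targets
are a config flag. One mask is drawn per step and shared across the batch.

Transfer copies every `encoder.*` checkpoint entry into the classifier by
key name (never by position); the decoder and mask token are discarded, and
the SE gate, head and (if learned) positional table keep their fresh
initialization. A shape or key mismatch raises naming the offending key.

## Data pipeline

**Augmentation** (training only): bicubic resize to `target_size`; horizontal
flip (p = 0.5); two operations drawn with replacement from a ten-operation
enhancement pool (auto-contrast, equalize, rotate, flip, solarize, posterize,
color, contrast, brightness, sharpness) at magnitude 9 of 10 bins, with the
usual rand-augment magnitude ranges; random erasing (p = 0.25) of one
rectangle covering 2-33% of the image (aspect ratio log-uniform in
[0.3, 3.3], integer rounding clamped so the realized fraction stays inside
the bounds), filled with uniform noise; per-channel standardization with the
ImageNet mean/std convention (the baseline transfers ImageNet weights, which
presume it). Evaluation: resize + standardization only. "Exposure
adjustment" maps to the solarize/posterize pair and "color balance" to the
color-enhancement factor — the nearest standard operators to those names.

**Schedule and optimizer.** AdamW (decoupled weight decay 5e-4), base
learning rate 6.25e-5 at full scale, linear per-epoch warmup over the first
20 epochs, then cosine annealing to `min_lr` (default 0; annealing steps per
epoch) until epoch 400. Toy runs shrink all three numbers. The
best-validation-accuracy checkpoint is kept, ties to the earlier epoch; an
empty validation split keeps the final state with a warning.

**Metrics.** Accuracy plus per-class and macro-averaged precision/recall/F1
(scikit-learn) and the confusion matrix with true classes as rows. Macro
averaging was chosen for the aggregates; classes absent from an evaluation
set are flagged and scored 0.

## Synthetic data

The generator emulates the gross structure of stained single-cell images:
pale lightly-textured background, one elliptical cell body with
class-specific hue (moderate saturation, per-image jitter of +-4 degrees),
a darker multi-lobed nucleus (lobe count, area fraction per class) and
additive cytoplasmic granular noise. Side lengths are drawn uniformly from a
range (default 64-256) so the resize path is always exercised; splits are
assigned per record by seeded draw (default 0.8/0.2 train/val). Per-class
counts follow the declared design exactly, including long-tailed profiles
scaled from real dataset tables. Generation is byte-deterministic per
(design, seed); PNG storage keeps IO round trips exact.

What it does *not* emulate: stain chemistry and illumination variation,
chromatin texture, cell-boundary irregularity, touching or out-of-focus
cells, or any real-morphology correlation between classes beyond the
declared hue/shape/granularity axes. Passing tests on this data demonstrate
that the pipeline is implemented correctly and can learn the intended cues —
not that the full-scale model reaches any particular accuracy on real blood
smears.

## Accounting conventions

Parameters: every trainable scalar (running-stat buffers excluded). MACs for
one forward pass: each linear/patch-embedding map counts
`output_elements * (fan_in + 1)` (bias included), each LayerNorm one MAC per
element; attention score/value matrix products, activations, softmax, the SE
gate and the classification/metric head are excluded. Under this convention
the 197-token ViT-base/16 counts 16.87 GMACs and the 196-token fusion
backbone 16.78 GMACs, matching the reference two-decimal figures, and
removing the class token strictly reduces the count.

## Scaled-down study conditions

CPU-scale runs used throughout the tests: toy backbone (32-pixel input,
patch 4 or 8, depth 2, width 32, 4 heads), 4-class synthetic sets of 40
images per class with 90-degree hue separation, MAE pre-training for 200-300
steps (batch 16, lr 1.5e-3) on the merged labeled+unlabeled image pool, and
fine-tuning for 80 epochs (batch 32, base lr 1e-3, 3 warmup epochs) — a
convergence-length schedule at this scale, mirroring the role of the
400-epoch full-scale schedule. Under these conditions the MAE-initialized
run ends at a lower training loss than the random-init run and both exceed
90% validation accuracy. This comparison is schedule-sensitive: with much
shorter fine-tuning the freshly-initialized model can reach a lower training
loss first, because transferred weights adapt to a new objective more slowly
than they pay off.

## Known limitations

* The autodiff engine is float64 and single-threaded beyond BLAS; full-scale
  (ViT-base, 224 px) training is supported in configuration but impractical
  on CPU; full-scale models are used for accounting only.
* `lr` schedule steps per epoch, not per iteration (the warmup is specified
  per epoch; the annealing granularity is a documented choice).
* The layer-fusion pooling order (pool-then-gate) is one reading of the
  architecture; gate-then-pool over full token grids is not implemented.
* Sub-center count, margins and scale are global config; no per-dataset
  auto-tuning.
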