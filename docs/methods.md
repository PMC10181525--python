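# Methods

## Problem and model

The package classifies leaf images into six states — Healthy and N, P, K,
Mg, Fe deficiency — by fusing two feature families before classification:

* **Shallow features** describe what an agronomist looks at: color
  (deficiency chlorosis shifts hue from green toward yellow/white) and
  texture (crinkling, reticulate patterning, vein contrast). They are
  explicit, interpretable, and need no training data.
* **Depth features** are the pooled, layer-normalized pre-classifier
  embedding of a convolutional network, supervised on the same task.

Serial fusion concatenates the two blocks. The premise, which the package
demonstrates on constructed data, is complementarity: when two classes are
(nearly) indistinguishable in the embedding, an explicit color feature can
still separate them, and a trainable head over the fused vector exploits
that.

## Segmentation

Iterative threshold selection (Ridler–Calvard): T ← (u₁+u₂)/2 where u₁, u₂
are the mean gray levels below/at-or-above T, iterated until |ΔT| < tol.
Defaults: init = global mean, tol = 0.5 gray levels, max_iter = 100. The
update with the *mean* of the region means is the standard fixed-point form;
for a two-valued image it converges to the midpoint of the two levels
exactly, which the tests assert. Foreground polarity is resolved by mean
color saturation (leaves are saturated, studio backgrounds are not), with
explicit overrides. Post-processing — morphological closing (3×3, 2
iterations), largest connected component, hole filling — is an extension
beyond plain thresholding: dark vein networks can dip below threshold and
slice the leaf into fragments, and closing bridges those thin gaps. The
closing is idempotent, so re-segmenting a returned mask reproduces it.

## Shallow features

* **HSI conversion** uses the geometric form: I = (R+G+B)/3,
  S = 1 − 3·min/(sum) (S := 0 for black), H = θ = arccos(...) for B ≤ G and
  2π − θ otherwise, H := 0 wherever S = 0. H is stored in radians in
  [0, 2π).
* **Color histogram**: 256 bins per channel over foreground pixels,
  channels concatenated H | S | I (768 values). 256 bins is forced by the
  768-dim contract. Histograms are L1-normalized per channel by default so
  the descriptor is invariant to leaf size; a raw-count mode is retained.
* **GLCM**: gray values (luminance 0.299/0.587/0.114) quantized to 64
  equal-width levels; pairs counted at distance 1 in the four standard
  directions with offsets (row, col): 0°→(0,+1), 45°→(−1,+1), 90°→(−1,0),
  135°→(−1,−1); **both** pixels of a pair must lie in the leaf mask, so
  background never contaminates texture. Matrices are symmetrized
  (p + pᵀ) and normalized. 64 levels keeps matrices well populated on small
  leaves; all parameters are configurable.
* **Statistics**: ASM Σp², contrast Σ(i−j)²p, correlation
  Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) (:= 1 when a marginal SD vanishes — the
  constant-image limit), entropy −Σp ln p (0·ln 0 := 0), IDM Σp/(1+(i−j)²),
  homogeneity Σp/(1+|i−j|); dissimilarity and energy are available as
  drop-in replacements since published feature lists vary. Default set:
  (ASM, contrast, correlation, entropy, IDM, homogeneity) at four angles,
  angle-major, 24 values.

## Depth backbone

The reference extractor is ConvNeXt-style: 4×4/stride-4 stem, four stages
of inverted-bottleneck blocks (depthwise 7×7 conv → LayerNorm → 1×1
expansion ×4 → GELU → 1×1 projection, residual), 2×2/stride-2 downsampling
with pre-norm between stages, then global average pooling followed by a
final LayerNorm whose output *is* the depth feature (1024-dim for
C = (128, 256, 512, 1024), B = (3, 3, 27, 3); 36 blocks). Stochastic depth
and layer-scale refinements of production ConvNeXts are deliberately
omitted — the block above is the reference unit. Pretrained weights are not
bundled; builders initialize from a seed and load user-supplied `.npz`
state dicts. Preprocessing: resize to the model's input size, scale to
[0, 1], standardize with fixed constants (mean 0.5, SD 0.25 per channel).
A three-convolution `TinyBackbone` (default 32-dim embedding, 64×64 input)
honors the same contract at test scale, and any callable
`images → (n, d)` can be plugged in as an external extractor.

All networks run on the package's own reverse-mode autodiff engine
(`leaffuse.autodiff`): float64 tensors, hand-written backward rules for
matmul, convolution (im2col; grouped/depthwise supported), pooling, softmax
and the elementwise ops, verified against central finite differences in the
test suite. Everything is single-threaded numpy, so runs are bit-reproducible.

## Fusion

[shallow | depth] concatenation, shallow first, z-scored per feature with
mean/SD (population convention) fitted **on the training split only**; the
fitting function rejects samples flagged val/test outright. Constant
features get an SD floor of 1 (they pass through centered). Standardization
is needed because histogram entries (≤ 1), raw Haralick statistics
(contrast can reach thousands) and network activations live on incompatible
scales; an unscaled mode preserves the literal concatenation.

## Heads

* **F-Net**: dense(hidden 512) → ReLU → dense(classes).
* **FC-Net**: the vector as a 1-channel signal → conv(k=3, c=8) → ReLU →
  max-pool(2) → conv(k=3, 16) → ReLU → flatten → dense(classes).
* **FA-Net**: zero-pad to a multiple of d_model (default 64), reshape to
  n tokens × d_model (824 → 13 tokens), one multi-head attention layer
  (h = 4), flatten → dense(hidden) → ReLU → dense(classes).

Tokenization by padding/reshaping is a design choice: a flat feature vector
has no canonical sequence structure, so no positional encoding is used and
the attention layer is permutation-equivariant (tested). One attention
layer, no internal residual or layer norm — the head is a recoder, not a
transformer stack. Softmax is applied at inference; training uses
categorical cross-entropy on logits. The same architectures applied to
shallow-only input are the S-/SC-/SA-Net variants.

## Training protocol

Mini-batch Adam, batch 8, 150 epochs by default, learning rate 0.001
stepped down to 0.0001 at the switch epoch (default 75; the published
protocol states initial/final rates without a schedule, so a single step at
mid-training was fixed as the reference). Shuffling, initialization and
batching are all driven by explicit generators seeded from the config, and
epoch-level train/val loss curves are recorded.

## Metrics

One-vs-rest reduction of the confusion matrix (rows = true class):
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) recomputed from the reported
P and R, Acc = correct/total, all in percent. AP is implemented as the
*mean* of per-class precisions so it lies in [0, 100]; the un-normalized
sum of precision fractions is also reported for reference. A class absent
from the evaluation labels is excluded from macro averages with a warning.
ROC curves and AUC (trapezoid rule) are one-vs-rest on softmax
probabilities via scikit-learn. Baselines: SVC(RBF, C=20, γ=1/(2·8²) — the
published "radius parameter 8" read as the kernel width σ) and
RandomForest(max_depth=13, min_samples_leaf=20, min_samples_split=120,
max_features=7); both accept parameter overrides.

## Synthetic data

The image generator renders one elliptical leaf (random orientation, a
midrib-plus-branches vein skeleton) on a dark textured background (mean
gray 30/255) and colors it in HSV from a per-class recipe: Healthy hue
120°; N 75° uniform yellowing; Fe 58° pale low-saturation reticulate mesh;
Mg 90° with yellow interveinal spots; K 105° with yellowed margins and high
roughness; P 140° dark green with reddish veins. Fe and N are deliberately
close in hue — the planted analogue of the real-world Fe/N chlorosis
confusion. Output images are uint8 PNG-compatible arrays with exact
ground-truth masks. Splits are stratified 7:2:1 (train/val/test) with
largest-remainder rounding, so the three parts always conserve the class
total exactly.

The feature-space generator skips images entirely: per-class isotropic
Gaussians in a (shallow | depth) block structure, with designated
*confusable pairs* whose depth-block means are made identical while shallow
means stay separated (default: one-hot means scaled by separation 3, unit
covariance). This isolates the fusion claim from image-processing noise.

What the generators do **not** emulate: real leaf shape variation, lighting
and shadow, specular highlights, background clutter, disease co-occurrence,
or the actual covariance structure of deep embeddings. Passing tests
therefore demonstrate correctness and internal consistency of the pipeline
and the fusion mechanism under controlled conditions — not field accuracy
on real orchard imagery.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately small
configurations chosen as sensible desk-scale experiments: 64×64 synthetic
leaves (10–20 per class), the tiny backbone fine-tuned for ≤ 8 epochs,
heads trained 40–60 epochs, and the cluster experiment with 60 samples per
class. The full-scale ConvNeXt-Base path is exercised for construction and
embedding extraction (its 1024-dim contract) rather than training.
Degenerate inputs are defined, not patched around: constant images are
rejected by the thresholder, empty masks by the extractors, sub-2-sample
fits by the standardizer; σᵢσⱼ = 0 defines correlation = 1; 0·ln 0 = 0 in
entropy. Ties in max-pooling resolve to the first maximum. All tolerances
asserted in tests are stated inline there.

## Known limitations

* The attention head treats an arbitrary zero-padded reshape as its token
  structure; other tokenizations (e.g. block-aligned) are unexplored.
* The numpy engine is CPU-bound; fine-tuning the full ConvNeXt-Base at
  224×224 is supported but slow, and no data augmentation is provided.
* The synthetic recipes are distinguishable by design; nothing here
  validates botanical fidelity.
* Multiclass accuracy is reported as correct/total (the binary
  TP+TN-form reduces to this under one-vs-rest averaging of a consistent
  predictor); per-class accuracies are available from the confusion matrix.
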