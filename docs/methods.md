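# Methods

This note records the scientific and numerical choices behind `cadeye`: what
each stage computes, which knobs matter, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## Preprocessing: fluorescence simulation

The transform is pure channel arithmetic: split → `G' = α·G` → merge
`(R, G', B)` → optional blue suppression → optional HOT colormap. Parameters:

- **α** (dimensionless, default 2.0) — green amplification. Values are
  scaled in float, rounded half-away-from-zero, and clipped to 255; clipping
  is our choice (the 8-bit contract must hold, and saturation of already
  bright green pixels is the natural behavior of an intensity stretch).
- **suppress_blue** (default on) — whether the classification experiments of
  the original CAD formulation ran with suppression enabled is not
  documentable, so it is a flag; the default pipeline keeps it on.
- **colormap** (`none`/`hot`, default `none`) — the HOT branch maps the
  *processed green channel* through a fixed in-repo 256-entry lookup table
  (black → red → yellow → white in equal thirds, endpoints exactly black and
  white). A fixed table keeps outputs bit-reproducible with no plotting
  dependency. The colormap is visualization-only: the classification path
  never consumes it.

With α = 1, suppression off and no colormap the transform is the identity;
the red channel is always bit-identical to the input (colormap aside). These
invariants are asserted in tests.

Resizing uses bilinear interpolation to 700 × 600 px, read as width × height
(arrays of shape `(600, 700, 3)`, rows = height everywhere in the package).
The width × height reading and the interpolation choice are ours; both are
pinned by tests so they cannot drift silently.

## Synthetic fundus generator

The generator renders, per image: a circular retinal field (warm base color
with radial falloff and low-frequency mottling), an optic disc with a
physiological cup (cup/disc area ratio 0.2), a random-walk vessel tree rooted
at the disc (6–9 main branches with one side branch each), sensor noise, and
a class signature:

- *diabetic retinopathy*: 25–45 dark-red dot hemorrhages plus 8–16 bright
  yellow Gaussian exudates;
- *hypertensive retinopathy*: vessel half-width 1 px instead of 4 px, plus
  5–9 soft cotton-wool patches;
- *glaucoma*: cup enlarged to cup/disc area ratio 0.72 (> the 0.6 clinical
  cut-off) **and** a pale peripapillary-atrophy crescent around the disc.
  The crescent was added during development: cupping alone occupies ~0.4 % of
  the image and is erased by global average pooling, which made glaucoma
  indistinguishable from normal for every pooled-feature classifier;
  peripapillary atrophy is an anatomically standard correlate of
  glaucomatous discs and gives the class a signature of realistic spatial
  extent;
- *contrast/cataract*: a global haze blend toward mid-gray with strength
  0.55, which strictly reduces intensity spread.

Images are rendered on a half-resolution canvas and bilinearly upscaled to
the raw size (default 1125 × 1264 px, width × height); all drawn structures
are larger than two pixels, so this trades unobservable detail for a ~4×
speedup. Everything is driven by `numpy` `SeedSequence`s keyed on
(seed, class), so images are bit-reproducible, including PNG bytes.

**What the generator does not emulate:** real optical blur and illumination
gradients, camera vignetting, anatomical variability (maculae, myopic discs),
disease-severity continua, label noise, and inter-source domain shift. A
pipeline that separates these synthetic classes demonstrates that its stages
are wired and trained correctly — not that it would classify clinical
photographs; the printed dataset-composition table is packaged for
bookkeeping precisely because the corresponding corpus cannot be shipped.
The packaged table reproduces its published cells verbatim, including an
internal inconsistency (one source row's cells sum to 4911 against a printed
row total of 4101; the grand total 65,871 matches the row totals, not the
column sums). It is flagged, never repaired.

## Augmentation and balancing

A policy is a list of sub-policies, each a sequence of
(operation, probability, magnitude-level) triples; one sub-policy is drawn
uniformly per image. Magnitude levels 0–9 map linearly onto bounded ranges
(rotation ≤ 15°, translation ≤ 10 %, shear ≤ 8°, photometric factors
1 ± 0.2, cutout ≤ 10 % area, crop keeping ≥ 85 % area). The default policy is
a fixed five-sub-policy table; learned policy search is out of scope, and a
fixed table is the only reproducible option. Geometric fills are black,
matching the black-bordered fundus field. Balancing oversamples minority
training classes with augmented copies (never undersampling, never touching
the test split, never deleting originals).

## Backbones

Two frozen convolutional feature extractors in NHWC layout, implemented
directly in NumPy (forward-only; there is nothing to backpropagate through a
frozen network):

- `mobilenet_v2_like` *tiny*: 3×3 stride-4 stem (8 ch, ReLU6), then inverted
  residual blocks 8→16 (s2), 16→24 (s2), 24→24 (s1, additive skip);
  24 output channels.
- `efficientnet_b0_like` *tiny*: same stem with swish, then MBConv blocks
  with squeeze-excitation 8→16 (s2), 16→24 (s2), 24→32 (s2); 32 output
  channels.

The stride-4 stem is a deliberate speed/fidelity trade: with global average
pooling downstream, early spatial resolution contributes little, and the
tiny pair processes a 600 × 700 image in ≈ 0.2 s on one CPU. The *full*
scale builds the canonical stage layouts of both families, but since no
pretrained weight zoo is reachable offline it warns and initializes from the
seed — useful for shape/compatibility work only. "Final convolutional layer"
means the output of the last convolutional stage, before any pooling.

Input normalization is per-channel scaling to [0, 1] (a per-image z-score is
available by config). Freezing is enforced structurally — no code path
writes to backbone parameters after construction — and verified by SHA-256
parameter checksums before/after every training run.

## Fusion heads and training

Pooled features are first standardized by fixed mean/std computed once from
the training features (non-trainable constants stored in the model; batch
normalization "as a preprocessing step" in the sense that the raw pooled
channels differ in scale by orders of magnitude). Fusion is concatenation by
default; element-wise sum and product are available, each preceded by a
learned linear alignment transform to a common width (needed whenever the
two backbones' widths differ, and kept even when they match so the
combination stays trainable).

- *basic* head: `Dense(128, ReLU) → Dense(K, softmax)`. Its trainable
  parameter count is exactly `(c_A + c_B + 1)·128 + 129·K` under
  concatenation, asserted in tests.
- *extended* head (default): three width-preserving dense blocks — on a
  pooled vector a depthwise convolution degenerates to a per-feature affine
  transform and max pooling to the identity, so each block is
  `BN(ReLU(w ⊙ x + b)) + x` — followed by `Dense(850) → BN → ReLU →
  Dense(K, softmax)`. The 850-unit layer replaces (rather than follows) the
  128-unit layer; the block widths equal the fused width, which is what
  makes the stated within-block skip connections well defined.

Batch normalization uses ε = 1e-5, biased batch variance, and running
statistics with momentum 0.9; training mode requires batch size ≥ 2.

Training is Adam (β₁ = 0.9, β₂ = 0.999) on categorical cross-entropy,
head parameters only. Defaults: 15 epochs, batch size 32, base learning
rate 3e-3 with cosine decay over the epoch budget, stratified 10 %
validation split, and restoration of the best-validation-accuracy epoch at
the end. The learning rate was chosen by measuring head accuracy against a
fully-converged linear probe on identical features: at 1e-3 the head was
visibly undertrained within the 15-epoch budget (0.81 vs 0.95 test
accuracy); 3e-3 closes the gap and is stable across seeds. Epoch count is
fully configurable; 15 is a desk-scale default between the two orders of
magnitude one finds quoted for systems of this type.

## Gradient-boosted-tree head

Multiclass softmax objective with one tree per class per round. Gradients
`g = p − onehot(y)` and Hessian diagonals `h = p(1−p)` are recomputed each
round; trees are fitted by exact greedy split search on the gain
`½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)]` with midpoint thresholds, leaf
weight `−G/(H+λ)`, and splits accepted only for gain > 1e-12. Base scores
are log class priors, so τ = 0 predicts the priors. Defaults η = 0.3,
λ = 1.0, τ = 50, depth 3 — boosting conventions, configurable. Exact greedy
search is deterministic given the feature order; ties resolve to the first
feature and smallest threshold. No histogram approximation or column
subsampling: the feature matrices here are hundreds × hundreds.

The tree head consumes, by default, the trained fusion head's penultimate
activations (850-dim for the extended head, 128 for basic); class
probabilities are available instead by config. An optional depthwise
convolution over the backbone feature maps before pooling is provided
(identity kernels reproduce the standard path bit-for-bit); it is off by
default, as a feature-map transform is the only well-defined reading of a
"depthwise convolution" step attached to a tree learner.

## Grad-CAM

Because every classifier input is a global average pool, the gradient of a
class logit with respect to feature-map cell `(i, j, c)` is spatially
constant: `∂logit/∂pooled_c / (H'W')`. The channel weights therefore come
from the head's analytic input gradient (chained through the feature
standardization), and the map is `ReLU(Σ_c w_c A_c)`, bilinearly upsampled
to the input size and min–max normalized, with an all-zero map passed
through unchanged (no division by zero). Maps are produced per backbone and
as their average; heatmaps are a diagnostic output — the classification
path never consumes them.

## Evaluation

Confusion matrix with rows = true class; per class, one-vs-rest
SE = TP/(TP+FN), SP = TN/(TN+FP), precision = TP/(TP+FP),
F1 = 2·prec·SE/(prec+SE); macro averages are unweighted class means (micro
aggregation equals accuracy for single-label tasks and is reported as such).
Zero-denominator rates are reported as 0 with an explicit flag, keeping
reports machine-readable. Recall is reported alongside sensitivity although
the two coincide. Model comparisons require an equal epoch budget across
configurations and emit one row of macro metrics per model.

## Problem sizes and reproducibility

The study-scale configuration used by the test suite and the acceptance
script is 100 synthetic images per class (425 train / 75 test after the
15 % stratified split), raw 1125 × 1264 px, resized to 700 × 600, tiny
backbones, 15 epochs — about four minutes end-to-end on one CPU. Smaller
configurations (8–50 per class, reduced resolutions) exercise the same code
paths in unit tests. Every random choice flows from a single integer seed
through `SeedSequence`s; two runs with identical config + seed produce
bit-identical reports, which is itself a test.

## Known limitations

- Frozen random-weight backbones are feature *projectors*, not learned
  representations; held-out accuracy on the synthetic classes says nothing
  about clinical performance (see the generator section).
- Held-out accuracy at desk scale varies by a few points across seeds
  (backbone initialization, data draw and head initialization all move with
  the seed); the 100-per-class configuration clears 0.90 for both heads at
  the pinned seed, with typical values 0.85–0.97 across seeds.
- The extended head's block widths and the 850-unit layer's position are
  design defaults where the architecture description is ambiguous; they are
  configuration, not claims.
- The boosting loop is exact-greedy only, O(features × n log n) per node;
  adequate for deep-feature matrices, unsuitable for very wide inputs.
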