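# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limits of the package. It states no measured number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Networks and training

**Layer algebra.** Convolutions are same-padded with stride 1, so an
n×m×c volume maps to n×m×k under k filters; kernels must be odd so the
padding is symmetric. Max pooling uses same padding with stride s, mapping
n to ⌈n/s⌉ (the canonical stacks use 3×3/stride-2 throughout; average
pooling is deliberately not used by any canonical spec). Fully connected
layers flatten their input volume. Shape validation runs the full algebra
at construction, so every mismatch fails before a single training step.

**Forward/backward.** The engine is written directly on NumPy arrays
(NHWC, float32): im2col + matmul convolutions, with the input gradient as
a full correlation against the flipped kernels; pooling caches argmax
indices and scatter-adds gradients; dropout is inverted (train-time
scaling by 1/(1−p)) so evaluation is a no-op. Gradients were verified
against central finite differences during development, and the forward
arithmetic is pinned in the test suite against an independent nested-loop
implementation (tolerance 1e−5 in float32).

**Losses.** Regression uses mean squared error; classification uses mean
cross-entropy on softmax probabilities, with the gradient taken at the
logits (softmax−one-hot) for numerical stability. The output layer carries
no activation in both cases.

**Initialization and optimization.** Xavier/Glorot uniform initialization,
bound √(6/(fan_in+fan_out)), zero biases; Adam with β₁ = 0.9, β₂ = 0.999,
ε = 1e−8. Defaults: learning rate 1e−3, batch size 16. `label_scale`
divides regression targets during training (10 for leaf counts, 100 for
ages in hours) so both tasks optimize at comparable loss magnitudes; the
scale is undone at prediction time and never affects reported metrics.

**Stopping.** The protocol keeps the classic 80–20 train/test split with
no validation set, so stopping is based on the training loss alone: when
the mean loss over the last `plateau_window` steps (default 500) improves
on the previous window's mean by a relative factor below
`plateau_tolerance` (default 0.01), training stops; `max_steps` bounds the
run regardless. Tolerance 0 disables the rule except when a window is
strictly worse than its predecessor.

**Determinism.** All randomness flows from one `numpy.random.Generator`
seeded per run; there is no global state. Runs are bit-reproducible on a
fixed BLAS/thread configuration (multi-threaded BLAS reductions could in
principle reorder sums; results in this package's test sizes have been
stable).

## Data pipeline

Images are kept at native resolution on load and resized (bilinear) to the
architecture's nominal input size at pipeline time, so one dataset can
feed several input sizes. Training applies brightness → contrast → random
crop → flips, in that order (photometric before geometric); evaluation
center-crops only. Both crop semantics are linear: fraction f removes f of
each side length (25% of 128 → 96; 10% of 256 → 230, offsets floored).
Photometric outputs are clipped to [0, 255] after each step; whether the
historical pipeline clipped or rescaled is not documented anywhere we
know of, and clipping is the conservative choice. The contrast pivot is
the per-channel mean. Per-image standardization divides by
max(std, 1/√n_pixels), so constant images map to zeros.

The train/test split permutes indices under an explicit seed and floors
the train size (⌊0.8·165⌋ = 132). Class names map to indices in
lexicographic order so the mapping is reproducible across runs and
machines. Pascal VOC boxes are converted from 1-based inclusive to
0-based min-inclusive/max-exclusive on read; multi-object annotations keep
the first object with a warning, matching the single-plant scope.

## Synthetic rosettes

The generator emulates the statistical structure of individual-plant
rosette benchmarks, not their photographic appearance. Each plant is a set
of filled serrated-ellipse blades on short brown petioles, placed at
successive multiples of the golden angle (137.5°) with ±4° jitter. Leaf
length interpolates linearly from 0.17·image_size at age 392 h to
0.28·image_size at 620 h (overridable via `leaf_length_px`), and within a
plant younger leaves shrink to 55% and sit closer to the center, forming a
spiral of rings; this radial staggering is what keeps angularly close
blades from merging at moderate counts. Blade pixels are the only pixels
whose green channel strictly dominates, so the green-dominant mask is an
exact segmentation and its connected components an exact count oracle
whenever blades are disjoint (empirically: counts up to ~12 at 64 px,
~13 at 96 px). At higher counts blades overlap — as real mature rosettes
do — and the count label remains the generative count, not the visible
component count.

Counts are drawn balanced over the style's range (5–20 Arabidopsis-like,
2–13 tobacco-like): each admissible value appears ⌊n/span⌋ or ⌈n/span⌉
times, shuffled. This guarantees the wide label coverage a small counting
study needs while keeping the marginal close to uniform. Ages are drawn on
392–620 h conditionally on the count with positive correlation (default
0.6) via a linear mixture whose weight is chosen so the nominal linear
correlation equals the configured value; counts being discrete makes the
realized correlation approximate. The five morphology classes offset blade
aspect ratio, petiole fraction and serration depth from a common base,
scaled by `class_margin`; at margin 0 all classes render identically
(verified bit-exactly in the tests), and the default margin 1 separates
them visually. Backgrounds are soil-brown, plain or with seeded low- and
high-frequency texture, constrained so no background pixel is
green-dominant; Gaussian pixel noise (default sd 3) is added last.

A `CapacityError` is raised when the requested count cannot be placed at
the minimum leaf size (angular capacity ≈ π·min_leaf_length) or when the
leaf length range cannot fit the frame.

**What the generator does not emulate** — and hence what passing studies
do not show about real data: photographic texture and specularity, leaf
venation and color gradients, perspective and pot edges, occlusion by
non-plant objects, and the label noise of human-annotated counts. Results
on the synthetic studies demonstrate that the pipeline learns and
evaluates correctly, not that it reaches any particular accuracy on real
benchmark images.

## Evaluation and robustness

MAD is computed on unrounded predictions; dispersion uses the population
(÷n) standard deviation. Signed-error histograms bin over [min, max] with
equal-width bins (default 20, right-inclusive last bin). The non-absolute
mean count difference is deliberately not part of reports, since over- and
under-prediction cancel; `per_sample_errors` is exposed for any diagnostic
that needs it.

The robustness protocol applies one seeded brightness shift and one
contrast adjustment per test image — with parameters (delta 75, contrast
0.5–2.1) strictly outside the training envelope (63, 0.2–1.8) on the
bright/high-contrast side — then evaluates through the ordinary
center-crop path. Because per-image standardization removes affine
photometric shifts exactly (up to clipping), a well-trained model's
distorted MAD is expected to sit close to, but above, the clean MAD; the
benchmark study reports clean, in-envelope and out-of-envelope MADs side
by side, averaging the distorted ones over five distortion seeds.

First-layer filter grids min-max normalize each filter independently to
0–255 (zero-range filters render mid-gray) and tile ⌈√k⌉ rows. Only the
first, RGB-input convolution can be visualized; deeper layers act on
abstract feature maps and are rejected rather than misleadingly rendered.

## Desk-scale study conditions

The benchmark studies in `phenonet.benchmarks` (shared by the test suite
and the acceptance script) use reduced problem sizes chosen once: 400
images at 64 px for counting (80 test), 300 for classification and age
(60 test), filter schedules of 8–16 per layer, 2000–4000 Adam steps at
batch 16, and the standard augmentation envelope during training. The
memorization study trains the full-size counting architecture (input
128 px, filters reduced to 8 per layer) on 8 samples with augmentation
off, plateau stopping disabled. These sizes keep a full pipeline run in
minutes on one CPU while leaving each task clearly learnable from the
synthetic signal.

## Known limitations

- Stride-1 same-padded convolution is the only convolution offered; the
  canonical stacks need nothing else, and the n×m→n×m shape rule is what
  makes the published layer tables well-defined.
- Filter counts per convolutional layer are not part of the published
  architecture tables; the default schedule (32, 64, 64, …) is an explicit
  configurable assumption.
- The mutant classifier follows the tabulated three-FC-4096 head; the
  two-layer variant described in prose is available via
  `compact_classifier=True`.
- Local response normalization, metadata fusion, transfer learning,
  detection and recurrent models are out of scope.
- Training on CPU in NumPy is adequate for the desk-scale studies but not
  for full-resolution, full-capacity runs on large datasets.
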