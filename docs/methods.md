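# Methods

This note records the models, conventions and numerical choices behind
the package, in the order data flows through the pipeline.

## Synthetic head images

The generator exists so that every downstream stage — pre-processing,
partitioning, augmentation, training, evaluation — can be exercised and
tested without clinical data.  Each head is a radial outline

    r(θ) = r_ellipse(θ) · clip(1 + taper·cosθ·sin²θ
                                 + 1.5·pinch·max(0, −cosθ)·sin²θ
                                 + irregularity·P(θ),  0.2, ∞)

rendered bright on a dark background with 3×3 subpixel supersampling
(edge pixels get fractional coverage, keeping mask moments close to the
continuous outline) plus clipped additive Gaussian noise.  P(θ) is a
seeded sum of harmonics 3–7 normalized to max |P| = 1.  The four knobs
map onto the four abnormal geometries:

| class | knobs (preset mean) | rationale |
|---|---|---|
| Normal | irregularity 0.05 | smooth oval, 17×11 px axes at 35 px |
| Tapered | taper 0.45, axes 19.5×9.0 | elongated with asymmetric width |
| Pyriform | pinch 0.5 | pear-shaped basal widening |
| Small | scale 0.6 | scaled-down oval (area ×0.36) |
| Amorphous | irregularity 0.5, wide spreads on all knobs, scale 1.15 | no common structure; unconstrained size |

Two modelling points deserve note.  First, a bare `taper·cosθ` radial
term is — to first order — just a translation of the outline (a limaçon
is a shifted circle), so it produces no measurable width asymmetry; the
`sin²θ` factor makes it a pure width modulation.  Second, a class whose
only signature is inflated variance cannot be selected by a
nearest-centroid rule, so Amorphous carries a mean size offset in
addition to its boundary irregularity; this is also the biologically
defensible choice, since it is the only class without a size
constraint.  With these presets a nearest-centroid classifier on three
crude shape features (foreground area, moment eccentricity, |skewness|
of mass along the major axis) reaches macro recall ≈ 0.72 — far above
chance (0.2) but far below the CNN, which is the regime the training
tests need: the task is learnable yet not trivial.

Orientation is drawn uniformly on [0, 360) so the orientation
normalization stage has real work to do.  All draws derive from a
single integer seed; identical configurations yield bit-identical
images and manifests.

What the generator does **not** emulate: staining texture, acrosome and
vacuole structure, uneven illumination, debris, or correlated
(non-Gaussian) sensor noise.  Tests passing on synthetic data therefore
demonstrate that the pipeline's mechanics and optimization are sound,
not that clinical-grade accuracy would be achieved on real stains.

## Pre-processing

Intensities are 8-bit values divided by 255; no per-image
standardization.  Foreground extraction is an Otsu threshold with
polarity chosen by area (the smaller side is the head), so both
bright-on-dark and dark-on-bright stains work.  Orientation
normalization rotates the second-central-moment major axis to the
vertical, heavier half down, with bilinear interpolation and
edge-replication fill; moments are computed from *soft* foreground
weights (graded boundary values), which removes most of the ~2°
discretization bias that hard-mask moments carry on 35-px frames, and
up to three refinement passes absorb the interpolation residual.  A
disc-like head (moment anisotropy < 0.05) has no defined axis and is
returned unchanged.  The high-resolution preset adds a centroid-
centered crop (default 90 px) with the window clamped to the frame.

## Partitioning

Stratified k-fold: a class with n records gets test-fold sizes
⌈n/k⌉ × (n mod k) and ⌊n/k⌋ × (k − n mod k); which folds receive the
larger share, and the record order, are seeded choices — the quota
*multiset* is guaranteed, the placement is not derivable from any
stated rule.  A fixture mode accepts explicit per-class per-fold quotas
to reproduce a published split verbatim.  The development set is
round_half_away(0.2 · n_c) records per class taken from the fold-1
training side — the fraction applies to the class total, which is the
convention that reproduces the published carve (e.g. 76 × 0.2 → 15,
656 × 0.2 → 131).  All rounding in the package is half-away-from-zero.
When several repeated runs are trained, the fold assignment and dev
carve stay fixed and only the run seed (base_seed + run index) varies;
repetition is read as repeated training, not repeated splitting.

## Augmentation

The space is integer rotations [−r, +r] (r = 5 for 35-px data, r = 25
for the high-resolution preset) × five translations (none, or
round(0.06·width) px left/right/up/down, edge-replicated) × two flips
(none, vertical), applied in that order.  Multiplicities follow
m_c = round_half_away(cap · n_min / n_c) with cap 110 — the full r = 5
space size and the largest multiplier consistent with the published
augmented totals, which this rule reproduces exactly across all folds
of both datasets; the cap stays 110 for the larger r = 25 space.  The
m_c-element transform subset always contains the identity (originals
appear exactly once) and is otherwise a seeded uniform sample; the
published record fixes only the counts.  Balance guarantee: augmented
class sizes agree within 10% whenever every class has ≳40 distinct
images; below that the integer multiplier is too coarse (documented
limitation).  Development and test images are never augmented.

## Network and training

Block D (dense multi-branch block): BN → LeakyReLU → 1×1 conv (128
filters) → shared BN → LeakyReLU → parallel 5×5 and 3×3 convs (32
filters each) → element-wise sum → concatenation with the block input.
This wiring is the only arrangement of the named addition/concatenation
operations that is shape-legal for any input channel count and yields
the printed per-component convolution counts (9/12/18/9; 53 total with
the stem and four transitions).  Block E (transition): BN → LeakyReLU →
1×1 conv with ⌊C/2⌋ filters → 2×2 average pooling, stride 2 (a trailing
odd row/column is dropped: 35 → 17 → 8 → 4 → 2).  The stem is a
pre-activated 3×3 convolution, 64 filters; the head is BN → LeakyReLU →
global average pooling → dense softmax with L2 penalty λ = 0.005 (the
only regularized layer).  'Same' padding everywhere so concatenation is
legal; LeakyReLU slope 0.3; LeCun-uniform initialization for kernels
*and* biases (limit √(3/fan_in), the layer's fan-in used for both).

Training: Adam with β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷ and per-step
inverse-time decay lr_t = lr₀/(1 + decay·t).  The recorded history
includes the L2 penalty in the loss.  Checkpoint selection keeps the
weights of the epoch with the lowest development loss; without a dev
set, the lowest training loss.  A non-finite loss raises a divergence
error naming the epoch.  Batch-normalization inference statistics are
exponential moving averages with momentum 0.9 — deliberately faster
than the common 0.99, because CPU-sized runs take only a few hundred
optimizer steps.  Determinism: structure, counts and inference on fixed
weights are exactly reproducible; training is reproducible on a fixed
platform (single numpy RNG per fit) but not guaranteed bit-identical
across BLAS implementations.

The engine is a self-contained numpy layer library (im2col convolution,
explicit backward passes, float32 throughout); every backward pass is
verified against central-difference gradients in the test suite.
Memory scales with batch × H·W × k²·C for the im2col buffers, which is
why the CPU presets use batch 32.

### Presets

| preset | stem / bottleneck / branch | repetitions | optimizer |
|---|---|---|---|
| full (default) | 64 / 128 / 32 | (3, 4, 6, 3) | Adam 5·10⁻⁴, decay 0.0055, batch 1024, 50 epochs |
| `SMALL_ARCHITECTURE` | 16 / 32 / 8 | (1, 1, 2, 1) | Adam 10⁻³, no decay, batch 32, 8 epochs |

The full preset matches the published training recipe and is intended
for GPU-scale runs on real data (the original takes ~18 h); the small
preset is the package's CPU-sized configuration — the bottleneck width
and optimizer settings are the package's own choices (standard
small-CNN values), and all CPU experiments and tests use it.  Problem
sizes used by the tests: 1500 synthetic images (300/class) for the
five-class learning check, 400 for the two-class check, 64 for the
memorization check, 30 for the end-to-end smoke experiment.

## Metrics

All scalar metrics come from the C×C confusion matrix (rows = true),
which may hold real values so that averaged row-percent matrices can be
evaluated directly; 0/0 cells report 0 with a warning, and classes
absent from the truth are excluded from macro averages.  Accuracy is
the class-size-weighted average TPR, identically trace/total and
identically micro-accuracy.  G-mean is √(recall·specificity) per class
— the reading consistent with published (recall, specificity, G-mean)
triples.  MCC uses the Gorodkin multiclass form; kappa the standard
(p_o − p_e)/(1 − p_e).  ROC/PR curves are one-vs-rest via
scikit-learn's threshold sweeps: micro-averaging pools all
(score, indicator) pairs; macro ROC averages per-class curves on a
fixed 201-point FPR grid; PR AUC uses step interpolation.  Report
tables round half-away-from-zero to integer percent, matching the
published presentation.  Averaged confusion matrices are averaged in
row-percent space.

One known ambiguity: headline macro precision computed *from* an
averaged percent matrix need not equal the average of per-run macro
precisions (averaging and the precision ratio do not commute).  The
package always computes matrix-derived values and additionally stores
every per-run metric row, so both readings are available.

## Experiment orchestration

`run_experiment` executes k × runs cells, each writing its metric row,
count and percent confusion matrices, training history and augmentation
manifest; completed cells are skipped on re-run, so interrupted
experiments resume.  Every artifact carries the configuration hash and
seeds.  The aggregate table appends mean and standard-deviation rows;
the report renders per-class TPR, accuracy and the macro averages from
the across-runs percent matrix.

## Limitations

- The synthetic generator's realism limits are listed above; no claim
  about accuracy on clinical stains is made or tested.
- The exact block topology beyond the printed layer counts, the stem
  shape, the downsampling operator and the decay-parameter reading are
  reconstructions constrained by those counts; they are the documented
  conventions of this package rather than established facts.
- The numpy engine targets CPU-sized runs; the full preset on
  1100-image augmented datasets (~32k images/fold) is impractical
  without substituting a GPU framework.
- Fold-quota placement and transform-subset choice are seed-dependent
  where the published record fixes only counts.
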