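# Methods

This note documents the models, algorithms and numerical choices behind
`hippofactory`, and what the synthetic phantoms do and do not establish.

## Synthetic hippocampus phantom

The phantom is a parametric curved tube ("banana"): along the
anteroposterior axis (voxel axis 1) a quadratically bent centerline carries
a circular cross-section whose radius tapers toward both ends.  The tube
interior is partitioned into a DG core (inner 45 % of the local radius)
surrounded by four angular sectors (SUB, CA1, CA2, CA3); the anterior and
posterior caps (default 18 % of tube length each) can be relabelled as
undifferentiated HEAD/TAIL classes, emulating rater protocols that do not
delineate subfields there.  The geometry is evaluated at *continuous*
coordinates, so the same phantom can be carved exactly on its native grid
or on any affinely posed scene grid without label-resampling artifacts.

Intensities are class mean × bias field + noise:

* class means (arbitrary units) are spread over [0.15, 1.0] with distinct
  values per class — the separability of a good T2w acquisition, idealized;
* the bias field is a fixed low-order polynomial `1 + a·P(u)`,
  `P(u) = (u₀ + u₁u₂)/2 ∈ [−1, 1]` over normalized coordinates, default
  amplitude a = 0.2 — the minimal multiplicative model that exercises
  Z-normalization;
* noise is additive Gaussian (default SD 0.05, i.e. ~7 % of the smallest
  class contrast).

All randomness flows from the single integer seed of the spec through a
named `numpy` Generator; the label map depends only on the geometry, never
on the seed, so different seeds differ purely in noise.

**Head scenes.** A scene (default 3× the phantom grid) embeds a left
phantom and its mirror twin at 4×4 voxel-affine poses, on top of a smooth
"head" ellipsoid whose position and scale follow the phantom poses (so a
global pose change moves the whole scene coherently — what a registration
algorithm needs to be able to recover).  The template/atlas pair is the
same construction at canonical poses, the atlas labelling left = 1,
right = 2.  Ground-truth poses and per-side bounding boxes are recorded.

**What the phantom does not emulate:** anatomical folding, partial-volume
mixtures, MRI physics (k-space, coil profiles), inter-rater label noise,
or realistic subfield volume distributions.  High phantom Dice therefore
validates the *machinery* (losses, fusion, bookkeeping, uncertainty), not
segmentation quality on real scans.

## ROI localization

Built-in registration is multi-resolution (subsampling factors 4, 2, 1 with
matched Gaussian smoothing) Powell minimization of the mean-squared
intensity error over translation + rotation (rigid; plus per-axis
log-scales for affine), rotations parametrized as rotation vectors about
the grid center.  It is intended for the synthetic scenes' broad monomodal
similarity basin; for real MRI an external tool can be substituted by
supplying an `AffineTransform` directly.  Atlas ROI voxels are mapped
through the transform; each side's box is the floor/ceil hull expanded by
`margin` (default 16) voxels and clamped to the grid — clamping, never an
error, because the margin is a safety heuristic.  Crops are Z-normalized
(error on constant crops) and center-padded with zeros to multiples of 8
(the value matching background after normalization up to the crop mean);
pad amounts are recorded for exact inversion.  Whether right crops should
be mirrored to left chirality is protocol-ambiguous; a `mirror_right` flag
exists and defaults to off.

## Network

Fully convolutional 3D residual U-Net, channel-first with an implicit
batch of one (the training recipe uses batch size 1 to accommodate
heterogeneous crop shapes):

* pre-norm residual blocks (two 3×3×3 convolutions, identity shortcut;
  channel changes happen only in the down/up-sampling convolutions, so no
  projection shortcuts are needed);
* downsampling by stride-2 kernel-2 convolutions doubling channels;
  upsampling by stride-2 kernel-2 transposed convolutions halving them
  (channel schedule `base_channels × 2^level`);
* attention-gated additive skips: the skip is projected to the gating
  resolution by a stride-2 convolution, combined additively with a 1×1×1
  projection of the coarser decoder features, passed through ReLU, reduced
  to one channel, squashed by a sigmoid and trilinearly upsampled — a
  per-voxel coefficient map in [0, 1] multiplied onto the skip;
* switchable normalization at every site: a softmax mixture of instance,
  layer and batch statistics (batch ≡ instance at batch size 1, but the
  three-way parametrization is kept);
* softmax head; the loss consumes probabilities (soft Tversky counts).

The whole network runs on a purpose-built numpy reverse-mode autograd
backend.  3×3×3 convolutions are computed as 27 shifted matrix products on
a zero-padded flattened grid (contiguous BLAS operands, no im2col gather);
the fused switch-norm node has an analytic backward.  All gradients are
verified against central differences in the test suite.  Model parameters
are float32; training a desk-scale member (depth 3, 8 base channels, 32³
crops) takes ~0.23 s per step on one CPU core.

## Training

Bagging: each of E weak learners (default 5) draws N observations with
replacement (seeds `master+1 … master+E`) and trains independently.
Optimization: AdamW (decoupled weight decay 1e-4 on weight tensors only),
one-cycle learning rate (linear warmup over the first 30 % of steps from
`lr_max/10` to `lr_max = 2e-3`, cosine anneal to `lr_max/100`), stochastic
weight averaging over end-of-epoch snapshots from the 75 % epoch mark, and
train-time augmentation drawn from the same transform family as test-time
augmentation (the train-time family is otherwise unspecified in the
underlying recipe; sharing it is the simplest consistent choice).
Non-finite losses abort with the step, learning rate and observation id.

Desk defaults (depth 3, 8 channels, 40 epochs, 32³ phantoms) are the
configuration the test suite trains end-to-end; the publication-scale
recipe (depth 4, 512 epochs, 822 observations) is the same code with
larger config values.  Magnitude pruning zeroes the globally
smallest-magnitude convolution weights to reach the requested sparsity
(default 0.70) within one weight; norm gains/biases and bias vectors are
untouched.

## Loss

Focal Tversky per class on soft counts (TP = Σ p·y etc., no argmax — the
counts stay differentiable), `L = (1 − TP/(TP + 0.7·FN + 0.3·FP))^γ`.
The focal exponent is γ = 3/4 by default and configurable: renderings of
the exponent in circulation are typographically ambiguous between 3/4 and
4/3, so the choice is explicit rather than silent.  With α = β = 0.5 and
γ = 1 the loss reduces exactly to one-minus-soft-Dice (a test oracle).
Classes absent from an observation's ground truth are skipped in the class
mean rather than scored as vacuous zeros.  Background is an ordinary
channel.  Protocol modulation happens in merged-group space: merge groups
sum probability channels (group id = smallest member id); inside head/tail
target voxels all subfield probability is pooled into the cap channel, so
a subfield prediction there is a true positive for the cap, while outside
those voxels subfield and cap predictions are scored normally.

## Inference

TTA draws each transform independently per version: horizontal flip
(p = 0.5), affine (p = 0.75; rotations ±10°, isotropic scale 0.9–1.1 about
the crop center), elastic (p = 0.5; Gaussian-smoothed displacement field,
σ = 4 voxels, peak 1.5 voxels).  Predictions are mapped back to native
crop space before voting — flips/affines by the exact inverse matrix,
elastic fields by the negated-displacement approximation (residual
mismatch ≲ 3 % of voxels on phantoms, measured in the tests).  Votes from
all members × versions form one stack; fusion is the voxel-wise plurality
vote with ties broken toward the lowest class id (deterministic and
documented).  The uncertainty map is the Shannon entropy of the vote
frequencies; the output is labelled *vote entropy* because the stack mixes
augmentation and ensemble variability, whatever the conventional
"aleatoric" label suggests.

## Metrics

DC and VS are exact integer-count formulas.  VS uses the standard
volume-only form `1 − ||A|−|B||/(|A|+|B|)`: printed renderings sometimes
show an intersection in the numerator, which contradicts the quantity's
definition (equal-volume disjoint masks must score 1).  HD is computed on
voxel-centre point sets of the full masks (matching the printed
definition; surface-only and HD95 variants are labelled extras), scaled by
voxel spacing, via `scipy.spatial.distance.directed_hausdorff`; tests
check it against a brute-force double loop.

## Lifespan analytics

NCS fits use the `patsy` `cr()` natural cubic regression basis (quantile
knots; the basis spans constants, so the intercept is dropped to keep the
design full-rank) under OLS; AIC selects the degrees of freedom over a
candidate range (default 3–7), ties toward the smaller df.  Inflection
detection runs kneedle on the fitted curve over a 0.5-year grid with
sensitivity 1.0: the curve is split into rising and falling segments at
the global-maximum *plateau* (first/last grid age within 2 % of the
maximum relative to the curve's range); each segment is normalized to the
unit square, canonicalized to concave-increasing, and local maxima of the
difference-from-chord above the sensitivity threshold are reported.
Splitting at the plateau boundary rather than the literal argmax matters:
fitted plateaus are gently humped, and an argmax split shortens the
falling segment, steepens its chord and biases the detected knee several
years late (observed on noiseless fits).  On cohorts of 1000 subjects per
sex with noise at 5 % of plateau, the decay-onset knot at age 70 is
recovered with mean 68.7 and SD 1.1 years.

Periods are the intervals between consecutive detected inflection ages
(merged across sexes within 2 years) plus the range boundaries; within
each period `volume ~ age * C(sex)` is fit by OLS (single-sex tables drop
the sex terms), and p-values are BH-FDR-adjusted across the family of all
(region, period, term) tests of one analysis.  The anteroposterior profile
normalizes slice positions to 0–100 % between the first and last non-empty
slice along the declared axis (default axis 1, never auto-guessed),
resamples per-slice subfield fractions onto a common 101-point grid and
averages across subjects; fractions sum to 1 at every position.

## Cohort generator

Volumes follow growth → plateau → decay trends: linear segments with
quadratic C1 blends of half-width 6 years at the knots (default knots 22
and 70 years), so the noiseless curve is continuous, piecewise-polynomial
of degree ≤ 3 and linear in the tails.  Default plateaus are on the scale
of adult subfield volumetry (DG 900 mm³, CA1 1300 mm³, CA2-3 500 mm³,
SUB 700 mm³, whole 3500 mm³); males carry a +5 % plateau offset and ~1.35×
steeper slopes — the sex-by-age interaction the period regressions must
detect.  Default noise SD is 40 mm³; analysis-stage recovery tests use 45
mm³ (5 % of the DG plateau).  Ages are uniform over 5–100 years, sexes
balanced.  Noise can in principle push a volume negative; values are
floored at 1 mm³ (never triggered under the defaults).

## Problem sizes in the test suite

The end-to-end benchmark trains 2 ensemble members (depth 3, 8 base
channels) for 40 epochs on 20 phantoms of 32³ voxels and evaluates 10
held-out phantoms under full 21-version TTA — small enough to run in
minutes on one CPU while still exercising every pipeline stage.
Simulation-based checks (AIC df recovery, interaction power, type-I
calibration) use 100 seeds each at the sample sizes stated above.

## Known limitations

* The registration optimizer assumes a broad monomodal MSE basin; it is
  not suitable for real multi-contrast MRI (plug in an external tool).
* The elastic-inverse approximation leaves a small residual; votes near
  strongly deformed boundaries carry that alignment noise.
* Phantom class contrasts make segmentation much easier than real tissue;
  absolute Dice values do not transfer to scanners.
* The kneedle knee is only identifiable up to the smoothness of the
  fitted spline near a trend change; reported inflection ages inherit that
  blur (≈ ±1–2 years under the test conditions).
* AIC df selection on spline bases that are not nested can escalate the
  chosen df when noise is far below the inter-basis approximation error.
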