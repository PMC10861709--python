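# Methods

This note documents the models and procedures implemented in `rbp`, the
choices made where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate.

## Montage geometry

Electrode positions are treated as points on (approximately) the unit
sphere with the vertex on +z.  Before any geometric operation, positions
are unit-normalized, which removes digitizer scale.  The 2-D projection is
azimuthal equidistant about the vertex: planar radius = polar angle
(radians), planar azimuth preserved.  This is the standard projection for
EEG topographic maps; it is injective for distinct (polar, azimuth) pairs,
commutes with taking channel subsets, and preserves the angular
neighborhoods that the splitting algorithm relies on.  Any other
topology-preserving projection would behave comparably, but exact region
boundaries would differ.

## Splitting a montage into regions

A montage split is generated by recursive angular partitioning.  At each
level, a region's member channels are ordered by azimuth around the
region's channel centroid, starting from a random angle θ₀; the ordered
list is cut into k contiguous groups whose sizes differ by at most one
(earlier groups absorb the remainder — any fixed rule works; this one is
deterministic given the ordering).  Sector boundaries are placed at the
angular midpoint between the last channel of one group and the first of the
next, with θ₀ itself as the first boundary.  Intervals are half-open
`[θ_lo, θ_hi)`, so sibling sectors tile the full circle and *any* 2-D point
belongs to exactly one leaf region — membership of channels from unseen
channel systems is always well defined and never an error.  Ties in azimuth
are broken by label order.

Stopping is evaluated **per region**: before a region is cut, the candidate
children are tested against the declared minimum-resolution system, and the
cut is accepted only if every child would contain at least `min_nodes` of
that system's channels, counted with the child's own geometric predicate.
A region that cannot be cut stays a leaf while its siblings may still
split.  Because feasibility is checked geometrically, the same split is
valid for every channel system at least as dense as the minimum-resolution
system near every region; the layer therefore guarantees registration of
that system (and denser nested systems) by construction, and raises an
explicit incompatibility error for anything sparser.  Default split-vector
pool: (3,3,3), (4,2,4), (2,4,2), (2,2,2,2,2), (3,2,3), (2,3,2), (3,4,2),
sampled uniformly per split.

## Pooling mechanisms

All four mechanisms map a region's `channels × T` block to one length-`T`
representation and are permutation-invariant in the channel dimension.

* **Average**: channel mean.
* **ROCKET channel attention**: each channel's frozen features are the
  proportion-of-positive-values and maximum of every random kernel's
  valid-mode dilated convolution output (all PPVs first, then all maxima, in
  kernel sampling order — the order is this package's convention and is
  persisted with the kernel set).  Kernel sampling: length uniform on
  {7, 9, 11}, standard-normal mean-centered weights, bias uniform on
  [−1, 1], dilation 2^e with e uniform over the integers that keep the
  receptive field within the bound (default 250 samples; default 1000
  kernels).  Kernels are shared across all regions and splits and never
  trained, so features are constant per (subject, channel) and computed
  once.  The importance score is a single bias-free linear layer
  `w_{i,j}ᵀ z_k`; softmax over the region's channels gives the weights.
  The convolution accumulates tap-by-tap in a fixed left-to-right order with
  the bias added last, making the feature values bit-reproducible against a
  naive loop implementation.
* **Continuous channel attention**: a channel-wise scoring network
  g: ℝ^{1×T} → ℝ^{1×T} (two Inception modules, two filters, plus a
  pointwise linear head — the head is this package's choice for emitting a
  per-timestep score; length is preserved by same-padding inside the
  modules), then a per-timestep softmax over channels.
* **Head-region pooling**: one region per split (chosen uniformly at random
  from the split's own seed stream at build time; no principled selection
  rule presents itself and the choice is recorded in the saved layer) emits,
  per target region, a search embedding
  `s = [(W₁Z) ⊙ softmax_channels(W₂Z)]·1` from its ROCKET feature matrix
  `Z` (features × channels).  Non-head regions embed each channel with the
  *same* `W₁` and weight channels by softmaxed cosine similarity to `s`;
  the head region itself is pooled with ROCKET attention.  Embedding
  dimension defaults to 64.  Cosines use an ε = 1e-12 guarded denominator;
  a zero-norm embedding yields similarity ≈ 0 with a logged warning.

Trainable weights (`w`, `W₁`, `W₂`, continuous scorers) are initialized
from a small-variance normal (σ = 0.01) on a dedicated seed stream.  All
softmaxes are max-subtracted.  Region representations are z-normalized over
time with ε = 1e-8 added to the standard deviation, so constant rows (e.g.
from zero-filled inputs) cannot produce NaNs.  Representations are stacked
in (split index, region index) order; the order is arbitrary but fixed and
persisted.

## Classifier and training engine

The downstream classifier is an InceptionTime-style network: Inception
modules (bottleneck 1×1 convolution, parallel convolutions of lengths
{10, 20, 40}, a max-pool branch with bottleneck, concatenation, batch norm,
ReLU) with a linear shortcut every third module, temporal global average
pooling, and a single linear unit.  Full-size defaults: depth 6, 32 filters.
The raw logit feeds a numerically stable binary cross-entropy; the sigmoid
is only applied for prediction.  Optimization is Adam (default 1e-4).

All of this runs on `rbp.nn`, a compact NumPy reverse-mode automatic
differentiation engine written for this package (tensors, dilated 1-D
convolution via strided windows, batch norm, max pooling, softmax, Adam).
Gradients of every non-trivial operator are verified against central finite
differences in the test suite.  The engine is float64 throughout and favors
correctness over speed, which bounds the practical network size — hence the
desk-scale configuration below.

## Synthetic study data

The generator emulates the evaluation setting end to end without any
external data: a Fibonacci-lattice montage of 129 electrodes on the upper
hemisphere with nested 65- and 32-channel subsets (prefixes of a
farthest-point ordering, preserving quasi-uniform coverage; labels stable
across subsets).  Each subject's recording is per-channel 1/f noise
(exponent 1, unit SD) plus white noise (SD 0.3) plus a subject-specific
band-limited 8–12 Hz oscillation whose spatial gain is a Gaussian (width
0.6 rad) in projected distance from a posterior effect center — a smooth
field, deliberately, so spherical spline interpolation is a meaningful
competitor.  Class 1 carries `amplitude_ratio` (default 3) times the
class-0 oscillation amplitude; ratio 1 is the exact statistical null.
Classes are balanced; everything is seeded.

Noise streams are keyed by (subject, channel label) and the oscillation by
subject alone, so restricting a base recording to a subset montage is
*identical* to generating on the subset directly — the channel-reduction
comparison is on literally the same data with fewer channels.

**Effect-size calibration.**  The oscillation amplitude (default 0.25
against unit-SD background) was calibrated so that the densest-system
(129-channel) cross-validated AUC lands near 0.9 — the regime where
classification is clearly learnable but not saturated.  At much larger
amplitudes every harmonization method reaches AUC ≈ 1.0 and the comparison
between methods becomes uninformative (everything ties at ceiling); the
calibration targets the base-system AUC only, a statistic common to all
methods, and was then frozen.

What passing these tests shows: the *relative* behavior of the three
harmonization strategies under channel reduction on data whose class signal
is spatially smooth, band-limited and stationary.  What it does not show:
performance on real EEG (no artifacts, no volume-conduction mixing beyond
the smooth gain, no inter-subject variability in spectra or anatomy), nor
absolute AUC levels comparable to any real dataset.

## Evaluation protocol

Stratified 5-fold cross-validation at subject level (stratification is this
package's choice; it stabilizes small balanced cohorts).  Within each fold
the non-test subjects are split 75/25 into train/validation.  Training uses
the densest system only; after every epoch the validation AUC is computed
on all channel-system versions and the parameters at the epoch with the
best *mean* are kept (the snapshot includes batch-norm statistics and any
trainable pooling parameters).  Test AUC is reported per channel-system
version.  AUC is the rank-based (Mann–Whitney) statistic with ties counted
one half.  The grid search sweeps `min_nodes × num_montage_splits` and
emits one row of per-system mean test AUCs per cell.

**Desk-scale configuration** (`ExperimentConfig.desk_scale()`), used by the
package's own evaluation runs and the acceptance script: 200 subjects,
128 Hz, 2 s windows, 10 epochs, Adam 1e-3, batch 32, classifier depth 2
with 4 filters, RBP with average pooling, 5 montage splits, `min_nodes` 2.
These sizes keep a full three-method, five-seed comparison on one CPU in
minutes.  The larger learning rate compensates for the short schedule
(~50 gradient steps); the full-size defaults (50 epochs, 1e-4, batch 16,
depth 6 / 32 filters, ROCKET attention with 25 splits and `min_nodes` 1)
remain available through the same configuration objects.

## Numerical choices and degenerate inputs

- Spline interpolation: kernel order m = 4, Legendre truncation N = 50,
  ridge λ = 1e-5 — customary stabilized values for scalp potentials; λ = 0
  recovers exact interpolation at coincident electrodes.  The bordered
  linear system is solved once and folded into a single mapping matrix;
  a condition number above 1e14 raises an error rather than returning
  garbage.
- Angular ties and boundary hits resolve by the half-open interval
  convention, never by error.
- A montage split that would end with fewer than two regions is an error;
  layer construction retries a degenerate split up to 100 times on fresh
  sub-seeds before failing.
- Serialization stores all floats either as JSON shortest-round-trip
  decimals (geometry) or base64-encoded IEEE-754 bytes (parameter arrays),
  with a SHA-256 checksum over the payload; reload is bit-exact and a
  tampered file is rejected.

## Known limitations

- The autodiff engine is single-threaded NumPy; full-size training (depth-6
  classifier, continuous attention at many splits) is possible but slow.
- Montage splits cover the full montage and never overlap; overlapping or
  partial-coverage partitions, learned region boundaries, multiple
  representations per region, and merging splits by anything other than
  concatenation are out of scope.
- The spline baseline targets the densest system only, mirroring the
  train-on-dense design.
- Synthetic recordings are stationary and artifact-free by design; see the
  generator section for what that implies about external validity.
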