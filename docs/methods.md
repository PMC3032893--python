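# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limits of `tractica`.  It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Group ICA of tractogram stacks

**Model.** Per subject `s` and seed voxel `v`, the tractogram is a row of a
data matrix `X ∈ R^{(nV)×p}` (subjects concatenated along the seed
dimension, `p` voxels).  `X = A S` with independent spatial sources `S` and
mixing `A`; the multi-subject assumption is that each component's mixing
column factorises as subject loading × seed loading, i.e. each pathway and
its seed cluster are consistent across subjects, with only their strength
varying.  This is the standard practical realisation of three-way
(tensorial) group ICA as concatenation ICA plus a per-component rank-1 SVD
of the reshaped mixing column; a full trilinear alternating fit is not
implemented.  The per-component `rank1_fit_fraction_`
(top singular value² / squared column norm) quantifies how well the
factorised model holds; on phantoms with amplitude-only subject
variability it is ≥ 0.998.

**Preprocessing.** Each row (one tractogram) is variance-normalised before
PCA so high-count seeds do not dominate the decomposition, then demeaned.
Zero-variance rows (seeds owned by no bundle when the noise floor is zero)
are left as zero rows.  Whitening uses a randomized SVD truncated at the
model order; retained eigenvalues and the detected rank are stored.

**ICA core.** Fixed-point negentropy maximisation, tanh contrast, symmetric
decorrelation, tolerance 1e-6, at most 1000 iterations; on
non-convergence the fit restarts with an incremented seed (up to 5
restarts, logged).  The core is cross-checked in the test suite against an
independent FastICA implementation on synthetic mixtures (matched
|correlation| > 0.99).

**Conventions.** Spatial maps are unit variance with positive skewness
(tract maps are non-negative structures, so signal lives in the positive
tail); the compensating sign flips are applied to the mixing column and
seed loadings so the reconstruction is unchanged.  Subject loadings are
unit norm with the scale carried by the seed loadings; their overall sign
is fixed so that the subject-loading sum is non-negative.

**Model order.** `estimate_n_components` counts eigenvalues above
`multiplier × median eigenvalue` (default multiplier 2.0), treating
eigenvalues below 1e-9 of the largest as numerically zero, with a floor of
1.  This is a deliberate heuristic stand-in for Bayesian order estimation:
exact on noise-free low-rank data, conservative (≤ 2) on i.i.d. noise,
and clearly labelled as a fallback — `n_components="auto"` warns when the
spectrum shows no usable gap and falls back to a configured default.

## Gaussian + gamma mixture thresholding

Component maps are modelled as `π0 · N(μ, σ²) + π1 · Gamma(α, β)` with the
gamma supported on x > 0 only (its responsibility is zero at or below
zero), i.e. only the positive tail is modelled as signal; no negative-tail
class and no shift of the gamma.  EM details:

* Initialisation: Gaussian moments from the central 80% quantile range;
  gamma moments from the positive tail above the 90th percentile;
  π1 = 0.1.
* M-steps: Gaussian closed form; gamma by the exact
  responsibility-weighted MLE — rate = shape / weighted mean, shape solving
  `log α − ψ(α) = log(weighted mean) − weighted mean of logs` by Newton
  iteration from the Minka closed-form start.  If the statistic is
  degenerate the previous gamma parameters are kept (a generalised-EM
  step).  The exact M-step is used instead of moment matching because it
  guarantees a non-decreasing log-likelihood trace, which is asserted in
  the tests; moment matching violates it at the 1e-4 level.
* Convergence: |Δ log-likelihood| < 1e-6 (or 200 iterations);
  thresholding with an unconverged fit emits a warning but proceeds.
* Thresholding keeps voxels with posterior signal probability strictly
  above the cut (default 0.5); values ≤ 0 are always background.  For a
  finite sample the maximum attainable posterior is strictly below 1 in
  exact arithmetic, but it saturates to 1.0 in floating point deep in the
  gamma tail, so "cut → 1 empties the mask" holds only within the
  representable range.

Parameter recovery, measured by the acceptance script on
0.8·N(0,1) + 0.2·Gamma(8, rate 2) draws (20 000 samples, 10 replicates):
π1 within ±0.004 and shape within ±8%, log-likelihood non-decreasing in
every replicate.

## Seed Z maps and the ICA parcellation

Seed loadings are standardised with the sample (n−1) standard deviation;
`z_v = (c_v − mean) / sd`, one-sided strict threshold, default 3.09 = the
standard-normal quantile at p = 0.001 (two printed conventions, 3.1 and
3.09, round to the same quantile; 3.09 is used throughout).  Z maps are
invariant to positive affine rescaling of the loadings.  No multiplicity
correction across seeds (by design: uncorrected p < 0.001).

Components are classified anatomically by intersecting their
mixture-thresholded map with each target ROI (≥ 1 voxel by default); a map
straddling several ROIs contributes to all of them.  The per-ROI
parcellation is the union of significant seed sets over the ROI's
components — a seed voxel may appear in several ROI maps, deliberately.

An important geometric constraint: a binary-like seed cluster occupying a
fraction q of the seed structure standardises to roughly
`sqrt((1−q)/q)`, so Z > 3.09 is attainable only for clusters occupying
≲ 10% of the seed mask.  The phantom therefore plants compact
sub-regions (~5% of the seed mask each), mirroring the situation where
each pathway seeds a small cluster of a much larger structure.

## Winner-takes-all baseline and the permutation test

Per subject, each seed is labelled by the target with the largest
streamline hit count (ties to the lowest target index, tie count logged;
below `min_count` hits the seed is unclassified).  Hit counts are
per-streamline target intersections when the tracker ran in target mode;
for direct-sampled stacks (no individual streamlines exist) the
visitation-count mass inside the ROI stands in.

Group maps: per target, the binarised subject memberships are tested
voxelwise against zero with a one-sample t statistic whose null is built
by flipping the signs of whole subjects — full enumeration of all 2^S
patterns when 2^S ≤ the permutation budget, otherwise Monte Carlo with the
identity pattern counted.  Zero-variance voxels take t = ±∞ by the sign of
the mean (t = 0 when all zero, hence never significant).  The test is
exact for sign-symmetric null data; binary 0/1 data are not sign-symmetric
(flipping a zero is a no-op), so calibration statements use zero-mean
exchangeable nulls.  The minimal attainable p under full enumeration is
1/2^S: α = 0.001 therefore requires S ≥ 10 subjects, which is why the
hard-segmentation study arm uses a 12-subject phantom while the ICA
recovery arm uses 6.

## The synthetic phantom

What it emulates, and the defaults (all configurable):

* **Geometry** — 24³ grid, 2 mm voxels; an ellipsoidal seed structure
  (~620 voxels); seven target ROI slabs on the grid boundary (six face
  centres plus one corner patch), mirroring seven cortical targets.
* **Bundles** — K = 3 quadratic Bézier tubes from compact seed
  sub-regions (radius-2 balls, ~33 voxels, disjoint by default; an
  overlap knob shrinks the sub-region centres toward each other until a
  requested shared-voxel fraction is reached) to distinct target ROIs.
  Tubes are rasterised with a Gaussian cross-section (σ = 1 voxel) whose
  skirt is truncated at 1% of peak and renormalised to unit mass; the
  binary support of the truncated tube is the ground-truth pathway extent.
* **Subjects** — 6 by default; per-bundle amplitudes i.i.d.
  lognormal(0, 0.5).  Subject variability is amplitude-only by default
  (matching the factorised group-ICA model); an optional spatial-jitter
  knob translates each subject's pathways by a uniform shift from
  {−1, 0, 1}³, emulating residual anatomical misalignment.
* **Counts** — per seed voxel, Poisson draws around
  `5000 × Σ_k amplitude_ks × pathway_k` over owning bundles (5000
  streamline-equivalents, the conventional per-seed streamline budget)
  plus a uniform noise floor of 2e-4 expected counts per voxel
  (≈ 0.06% of the streamline budget straying off-pathway).  The floor is
  deliberately small so that population tract masks are tract-dominated;
  with a large floor the 25%-of-subjects mask fills with background
  voxels, a regime in which across-threshold overlap trends invert.
* **Orientation field** — bundle tangents with von Mises–Fisher
  concentration 40 on tube supports, isotropic background (κ = 5), for the
  streamline tracker.

What it does **not** emulate: diffusion-weighted signal, tensor/ball-and-
stick fitting and its MCMC posterior, registration error beyond integer
jitter, anatomical tract geometry, partial-volume effects, and the
spatially correlated wander of real probabilistic trackers.  Passing tests
therefore demonstrate correctness of the pipeline's statistics and its
behaviour under the stated generative model — not performance on real
diffusion data.

The across-threshold overlap trends (Dice decreasing, proportion-of-volume
increasing as the population threshold rises 25% → 50% → 75%) are driven
by inter-subject variability of apparent tract extent; the trend study arm
therefore enables spatial jitter (8 subjects).  With amplitude-only
variability the per-subject binarised masks are nearly identical and the
trends degenerate to ties.  Per-component strict monotonicity of Dice
additionally depends on how much of the jitter-blurred fringe the mixture
threshold keeps, which varies with the fitted background width; the
acceptance script reports the per-threshold means (the table analogue)
rather than a binary monotonicity flag.

## Tracking

A deliberately minimal tracker, built for oracle testability rather than
fidelity: nearest-voxel orientation lookup (no interpolation), step 0.5
voxels, per-step direction sampled from a von Mises–Fisher distribution
around the voxel axis via the closed-form inverse CDF of the axial cosine,
antipodally symmetrised by choosing the sign that minimises the turning
angle.  The first step follows the stored orientation sign, making the
zero-dispersion limit exactly a one-sided ray march (the oracle used in
tests).  Termination: grid exit, step budget (200), curvature above 80°,
or undefined field; contact with any exclusion mask rejects the whole
streamline.  Each surviving streamline increments a visited voxel once
(visitation, not dwell time).  Two-fibre voxel models are out of scope.

## Stacks and I/O

Stacks are 4D arrays (grid × seeds) with a seed table in the canonical
x-fastest scan order; subjects of one study must share grid, seed table
and space tag.  Downsampling reduces non-overlapping blocks by the mean
(resolution-independent intensity; exact global-mean preservation for
even divisions; trailing partial blocks averaged over their actual size).
Arbitrary-grid resampling is delegated to standard imaging tools.  I/O:
NIfTI via nibabel with affines preserved, TSV seed tables
(volume_index, i, j, k; 0-based), JSON sidecars for ground truth, mixture
fits, whitening records and provenance.

## Problem sizes and determinism

The shipped study conditions (24³ grid, ~620 seeds, 3 bundles, 6–12
subjects, 5000 streamline-equivalents) run the full pipeline in well under
a minute per arm on one CPU; the permutation calibration uses S = 12 with
full enumeration (4096 patterns) over 20 000 voxels.  Every stochastic
step takes an explicit seed; the CLI fans one global seed out to stages by
fixed offsets, and rerunning any stage with the same config is
byte-identical.
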