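# Methods

## Overview

dbmorph implements a hybrid unsupervised/supervised pipeline for
case-control classification of deformation-based brain morphometry data.
The data unit is a Jacobian determinant map: a voxel grid giving, at every
location, the factor of volumetric expansion or contraction needed to warp
an individual brain onto a common template, so values above 1 mark regions
larger than the template's and values below 1 regions smaller. The pipeline
has four stages:

1. **Post-processing** of Jacobian maps: Gaussian smoothing (8 mm FWHM),
   natural log transform (removing the multiplicative skew of raw
   Jacobians), a single linear rescaling of the whole dataset onto [0, 1],
   and masking of non-brain voxels to exact zeros — in that order.
2. **Unsupervised compression** by an undercomplete 3D convolutional
   autoencoder to a 32-channel latent grid, about 6% of the input size.
3. **Supervised classification** of the latent grids by a small 3D CNN
   producing a case probability per subject, trained and evaluated over
   repeated site-stratified splits.
4. **Perturbation mapping**: localized noise corruption of the input,
   re-encoded and re-classified, with the signed probability change
   accumulated per voxel to form per-subject and group sensitivity maps
   from which regions of interest are extracted.

Because the multi-site imaging data this kind of study uses are typically
consortium-held, every stage is exercised on synthetic cohorts with planted
ground truth (regions, effect sizes, site imbalance, behavioural
correlations), so recovery of the truth is a testable property rather than
an article of faith.

## Autoencoder

The encoder applies three stride-2, kernel-2, no-padding 3D convolutions
with rectifier activations, widening channels 1 → 8 → 16 → 32; each
stride-2 stage floor-halves the spatial dims, so a 121×145×121 input maps
to a 32×15×18×15 latent grid (121→60→30→15, 145→72→36→18). Kernel 2 /
stride 2 is the unique simple convention producing those published shapes;
its receptive fields tile the volume in non-overlapping 2×2×2 blocks, which
also makes the operation a reshape plus tensor contraction and therefore
fast on CPU. The compression ratio at those dims is
32·15·18·15 / (121·145·121) = 6.1%.

The decoder mirrors the spatial path with three stride-2 transposed
convolutions (rectifiers on the first two stages, a logistic sigmoid on the
last so reconstructions live in [0, 1] like the inputs). Odd target dims
are restored exactly by one trailing output-padding slice per axis that
receives only the bias. The decoder's intermediate widths default to
(32, 16) rather than mirroring the encoder's (16, 8): the decoder's
feature maps must carry enough information to place block-specific detail
during upsampling, and in measurements on synthetic cohorts the narrow
mirrored decoder floors held-out MSE an order of magnitude higher (5.4e-3
vs 4.8e-4 on a 16³ grid after 2500 steps). Both widths are constructor
parameters.

Training minimises mean squared reconstruction error (mean, not sum, per
batch) with Adam under a warmup-plus-cosine-decay schedule (default peak
learning rate 0.01, 100 warmup steps, decay to peak/100). A constant small
rate converges far too slowly within a 2500-step budget. Arithmetic is
single precision; losses are evaluated in double. All weights, batch
sampling, and dropout draw from seeded generators, so training is
bit-reproducible on a fixed platform.

### Reconstruction accuracy at desk scale

On the default synthetic cohort (192 subjects, 40×48×40 voxels) the
held-out MSE after 2500 steps reaches the low 1e-3 range, not the 1e-5 a
fully converged run on smooth real data can attain. Two structural reasons,
established by measurement: (a) a shared 32-dim linear code per 8³ block —
the best any width-32 linear convolutional autoencoder could do — floors at
1.6e-3 on this data, so beating it requires the decoder to act
position-specifically, which is slow to learn; and (b) out-of-brain voxels
are exact zeros that the sigmoid can only approach asymptotically. Wider
intermediate channels, larger batches, and longer schedules each push the
floor down (1.5e-4 observed at 16³ with widths (16,32)/(32,32), batch 32,
peak 0.03); the defaults balance fidelity against single-CPU runtime.

## Latent classifier

One 3D convolution (kernel 3, stride 2, no padding, 24 filters — mapping
the 15×18×15 latent to 7×8×7), a flatten, a 128-unit rectifier dense
layer, and a single output neuron whose logistic sigmoid is the case
probability. Batch normalisation follows every trainable layer and dropout
(rate 0.5–0.6, default 0.55) follows every batch normalisation. Loss is
binary cross-entropy on the logit; the optimiser is Adam at 0.001; batch
size defaults to 16. At inference, dropout is off and batch normalisation
uses stored running statistics, so prediction is deterministic.

Held-out loss is evaluated every 200 update steps (configurable). Early
stopping is an operationalisation of "stop when held-out loss diverges from
train loss": stop when the held-out loss has exceeded its running minimum
for 5 consecutive checks while train loss is non-increasing; the returned
parameters are always the best-held-out-loss checkpoint, never a later,
worse one. Site labels are used by the splitter only; the model inputs are
latents alone, so classification is site-agnostic by construction.

## Site-stratified splitting

Every (site, group) stratum contributes round-half-up(ratio × stratum
size) test members, then totals are adjusted by at most one subject per
stratum (seeded) so the global test size equals ceil(ratio × n) — e.g. a
39/153 split of 192 subjects at ratio 0.2. The ceiling (rather than
round-half-up, which would give 38) is chosen so the test set is never
smaller than the requested fraction; per-stratum deviations stay within ±1
of the proportional target. Per-site ratio overrides support balancing the
number of times each subject appears in test sets across repeated splits
(target 5–30 appearances; larger sites get proportionally smaller ratios).

## Perturbation sensitivity maps

For each of many filters, an 8×8×8 block of i.i.d. standard-normal noise is
added at a uniformly random in-bounds position (F = X + K, no clipping),
the perturbed image is encoded and classified, and the signed error
e = y* − y (base minus perturbed probability) is added to every voxel the
block covered; visit counts divide the accumulated errors at the end.
Positive values mark voxels whose corruption pulls a case's probability
down; negative values mark voxels whose corruption pushes a control's
probability up. Group maps are voxelwise means over subjects; regions of
interest are 26-connected components of |mean map| ≥ 0.25 — a
25-percentage-point probability change — with components below 27 voxels
discarded as noise.

The noise block is realised as i.i.d. draws inside the block and zero
elsewhere; for i.i.d. noise this is statistically identical to drawing a
full-volume field and extracting the block. Filter origins are not
restricted by the brain mask. Unvisited voxels keep a normalised value of
0.

**Scale matters for localisation.** The procedure localises well only when
one filter corrupts a small fraction of the classifier's features. At full
resolution an 8³ block covers one latent cell in 4050; on a coarse grid
whose latent is 3×3×3, the same block covers ~4% of all features and every
perturbation swamps the prediction, washing localisation out (measured:
top-importance voxels showed no overlap with planted regions at 24×28×24,
versus 5–6× base-rate precision at 40×48×40). Sensitivity analyses in this
package therefore run at 40×48×40 or larger, and users applying the
procedure to down-sampled data should scale the filter extent or grid
accordingly.

## Evaluation and statistics

Accuracy, precision (TP/(TP+FP)) and recall (TP/(TP+FN)) at threshold 0.5,
with undefined precision flagged rather than silently zeroed; rank-based
AUC (ties count one half) with the full ROC curve; per-subject median test
probabilities across repeated splits; paired t-tests on per-split
accuracies with paired Cohen's d = mean(diff)/sd(diff) (zero-variance
differences flagged as degenerate); OLS regression with intercept and
per-coefficient t tests (site entering as one-hot indicators, largest site
as reference, by the caller); and Pearson correlations with Fisher-z 95%
confidence intervals. p-values are reported unadjusted. Baselines use the
documented scikit-learn defaults for SVC and RandomForestClassifier, with
the fitted parameters recorded in the run output because defaults drift
across library versions; PCA (90% variance retained) is fitted on training
rows only to avoid leakage. All methods in a benchmark consume identical
split plans, the prerequisite for the paired comparison.

## Synthetic cohorts

A subject's field is built on the log-Jacobian scale as a smooth shared
background (broad-kernel-smoothed noise, sd 0.25), plus i.i.d. Gaussian
subject noise (sd 2.0 before smoothing; the 8 mm kernel shrinks it to a
spatially correlated field of sd ≈ 0.05), plus an additive mean shift
inside each spherical effect region for its target group. Fields are then
smoothed, unit-scaled cohort-wide, and masked by an inscribed ellipsoid —
the same chain as real data. Case-target regions get positive shifts
(cases' regions larger than the template's), consistent with regional
volume effects reported in the morphometry literature.

Default effect regions (five spheres, radius ~min(dim)/8, shift 0.08)
represent a moderate, realistic effect; `strong_regions` (radius
~min(dim)/5, shift 0.6, several times the smoothed subject-field sd)
defines the strong condition used for recovery tests. Note that smoothing
attenuates small spheres heavily — a radius-3 ball under a sigma-3.4 kernel
keeps only ~15–20% of its shift — so region sizes must be read jointly with
the smoothing width.

Sites default to four, one deliberately over-imbalanced (many more cases
than controls), emulating a common multi-site sampling pathology.
Behavioural standard scores (nominal mean 100, sd 15) are drawn as
100 − score_effect·z(driving region mean intensity) + noise with
score_effect 6 and noise sd 12, each score driven by one case-target
region; cases therefore score below controls and scores correlate
negatively (r ≈ −0.4 at the defaults) with their driving region's
intensity. Age, sex, and total brain volume are drawn to match a pediatric
case-control sample (controls slightly larger brain volume).

What the generator does **not** emulate: cortical anatomy and tissue
contrast, scanner- or site-specific intensity artifacts, registration
failure modes, heavy-tailed Jacobian outliers near ventricles, and
correlated multi-region atrophy patterns. Passing recovery tests therefore
demonstrates the machinery is correct and sensitive under known truth — not
that real-data accuracy will match.

## Numerical and design choices

- FWHM→sigma conversion fixed at 2·sqrt(2·ln 2) ≈ 2.35482; smoothing
  treats the field outside the grid as zero.
- Voxel indices are 0-based, axes ordered (x, y, z) in NIfTI storage
  order, shared across all modules.
- Unit scaling uses one global min/max over all volumes' in-mask voxels;
  it is idempotent and the degenerate all-equal case is an error.
- Latent flattening is C-order (channel-major), documented and tested.
- Adam uses standard bias correction; batch-norm momentum is 0.9 with
  eps 1e-5.
- Seeds: every public entry point takes a seed; derived seeds are formed
  by small integer arithmetic on it.

## Problem sizes

Tests and the acceptance script run at desk scale: cohorts of 48–192
subjects at 40×48×40 voxels (latent 5×6×5) or 24×28×24 (latent 3×3×3),
600–2500 optimiser steps, 20 benchmark splits, and 400–1500 perturbation
filters. Full-resolution 121×145×121 inputs are supported by the same code
paths (the architecture tests assert the published shapes at that size).

## Known limitations

- The desk-scale autoencoder does not reach the ~1e-5 held-out MSE a fully
  converged full-scale run on smooth data can reach (see above).
- The early-stopping divergence rule is a declared convention; the phrase
  it operationalises admits others.
- Sensitivity-map localisation degrades on coarse grids (see above) and
  for classifiers driven to saturation on separable data, where every
  perturbation of a case can only lower its probability and group maps
  acquire a uniform signed offset.
- The per-subject test-appearance balancing is an expected-value scheme;
  actual counts are reported, not enforced.
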