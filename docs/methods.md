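# Methods

This note records the models, conventions and numerical choices behind
`oarteval`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## Evaluation design

The unit of analysis is the treatment *session* (one fraction of one
patient). Each session carries two structure sets — the clinically corrected
contours (`clin`) and the automatically proposed contours (`auto`) — and two
dose distributions, each re-optimized on one of the structure sets. Two
comparisons are made per session:

1. **Geometric**: `auto` vs `clin` contours for the influencers (bladder,
   rectum) and the boost CTV.
2. **Dosimetric**: both dose arms evaluated on the *clinical* contours.
   The clinical contour is the ground truth throughout; evaluating the auto
   dose on the auto contours would hide exactly the delineation errors the
   comparison is meant to expose. (Evaluation on the auto contours remains
   available as a diagnostic flag.)

All masks of a session share one grid frame (voxel-center convention,
0-based indices, world position = origin + index·spacing). Dose grids may
live on their own frames and are resampled trilinearly to the structure
frame; query points outside the dose grid receive 0 Gy and are counted as a
warning, since silent extrapolation would corrupt coverage statistics.

## Geometric metrics

The surface of a voxelized structure is the set of world centers of set
voxels with at least one face-adjacent unset (or off-grid) neighbor. Both
95%HD and MDA are computed from the *pooled symmetric* multiset of
nearest-neighbor distances (A→B and B→A concatenated), with anisotropic
spacing respected. A directed variant is exposed, but pooled-symmetric is
the default: the field uses both conventions, a single multiset serves both
metrics, and pooling makes the two metrics provably symmetric under swapping
the arms. Percentiles use linear interpolation of order statistics
(rank = 1 + (n−1)·p), which is numpy's default and is pinned by tests.
Nearest distances use a k-d tree; a brute-force all-pairs oracle in the
test suite confirms exact equality on random mask pairs.

Voxel-center surfaces (rather than marching-cubes meshes) were chosen
because they are deterministic and oracle-checkable; mesh surfaces would
introduce interpolation choices that tests cannot pin down. The price is a
half-voxel quantization of all distances, acceptable at the 2 mm default
grid of the phantom.

## Dosimetry

V95% of a structure is the fraction (and absolute volume) of its voxels
with dose ≥ 95% of the prescription, *inclusive* at the threshold
("a minimum of 95%"), and the clinical requirement check is likewise
inclusive at 98%. Boost structures (GTV, CTV_boost, PTV_boost) are judged
against the boost prescription (55 Gy total = 2.75 Gy/fraction), elective
structures against the elective one (40 Gy = 2.0 Gy/fraction). Coverage is
evaluated per fraction by default; the total scale is a configuration
switch and is equivalent whenever the dose grids are exact per-fraction
multiples.

The spill is defined as `V95,out = V95,body − V95,target` (absolute
volumes), a definitional identity that tests assert on every record.
Which prescription level defines `V95,body` when two dose levels coexist is
genuinely open; the default is the *elective* (lower) level, so spill is
never negative for elective targets, and a per-target ("own") level is
available as a config alternative.

The DVH is a plain voxel-count cumulative histogram without sub-voxel
partial-volume weighting, consistent with the mask-based geometric metrics;
partial-volume weighting would require contour geometry that the internal
bundle format deliberately does not retain.

## Statistics

Arms are compared per structure/metric with a paired two-sided Wilcoxon
signed-rank test. Zero differences are discarded (classical convention) and
reported separately; absolute differences are ranked with average ranks for
ties. For up to 20 effective pairs the two-sided p-value is exact: the null
distribution of the positive rank sum over all 2^n sign assignments is
built by polynomial convolution (mathematically identical to enumeration,
which the tests verify against an explicit-enumeration oracle up to
n = 12). This matters because tied ranks are common in coverage data and
textbook exact tables (and scipy's exact method) assume tie-free ranks.
Above 20 pairs a normal approximation with tie-corrected variance and
continuity correction takes over; at n = 20 the two agree to within 0.01 on
tie-free data.

The family-wise level is Bonferroni-corrected, α/m with α = 0.05 and a
configurable family size defaulting to 10 (corrected level 0.5%). Which
comparisons form the family is a reporting choice, not a property of the
data, hence configuration.

## Stratification

For each session the *influencer volume difference* is
|V_reference − V_online| (cm³) between the reference-CT contour volume
(session metadata) and the online clinical contour volume. The absolute
difference is the default — the direction of a bladder-volume mismatch is
secondary to its magnitude for propagation quality — with a signed variant
available. Sessions fall into half-open bins [k·w, (k+1)·w) with w = 50 cm³
for the bladder and 25 cm³ for the rectum, four bins, the last open-ended;
per bin the percent of sessions failing the CTV coverage requirement under
the auto dose is tabulated.

## Synthetic cohort

The phantom emulates the *statistical structure* of a paired oART study,
not patient realism:

* **Grid**: 96 × 96 × 88 voxels at 2 mm isotropic. 2 mm keeps a
  340-session cohort at desk scale while keeping ellipsoid voxelization
  error below ~2% for organs ≥ 100 cm³.
* **Anatomy per patient**: body ellipsoid; bladder ellipsoid with fixed
  axis ratios sized to a reference volume drawn from 150–280 cm³; a curved
  rectal tube (radius 9–16 mm) posterior to the bladder; a spherical tumor
  bed (GTV, radius 15 mm) seated on the postero-inferior bladder wall.
* **Margins** (clinical protocol of the evaluated workflow):
  CTV_boost = GTV ⊕ 5 mm, PTV_boost = CTV_boost ⊕ 5 mm,
  CTV_elective = bladder ∪ CTV_boost (the lymph-node component of the
  elective CTV is deliberately omitted — the analysis pipeline is agnostic
  to how a mask arose), PTV_elective = (bladder ⊕ 7 mm) ∪ PTV_boost.
  Margin expansion is Euclidean on voxel centers with anisotropic spacing.
* **Session-to-session variation**: online bladder volume = reference +
  day-to-day variation (SD 55 cm³) + filling at 1–4 ml/min over a 10–25 min
  on-couch time; the day-to-day SD is chosen so the reference-to-online
  differences populate all four 50 cm³ stratification bins, as the clinical
  distribution does. Rectal caliber jitters with SD 2.5 mm.
* **Auto-contour discrepancy**: the signed distance of each clinical mask
  is offset by amplitude × smooth unit-bounded noise (Gaussian-correlated
  at 15 mm, tanh-squashed to (−1,1)) and re-thresholded at zero, so the
  surface never moves farther than the amplitude. The per-session amplitude
  is drawn from 1–3 mm plus 1.5 mm per 100 cm³ of bladder volume change —
  emulating the degradation of influencer-guided propagation under large
  anatomical change. The propagated boost additionally receives twice the
  amplitude, a systematic 1.7 mm shrinking bias (automatic boost volumes
  run small), and a rigid positioning error of up to 2 mm plus 5 mm per
  100 cm³ of bladder change. The auto GTV is the auto CTV_boost eroded by
  the 5 mm margin, preserving the containment chain by construction.
  These magnitudes were chosen to land the per-structure DSC/MDA/relative
  volume medians in the range reported for AI-proposed pelvic contours
  (bladder DSC ≈ 0.93, boost CTV DSC ≈ 0.7, relative volume ≈ 80%).
* **Dose model**: geometric, not physics-based — each prescription level is
  delivered uniformly inside its PTV and halves every 5 mm of Euclidean
  distance outside it; the voxel dose is the maximum over the two levels.
  The evaluation needs realistic DVH structure near the target boundary,
  not beam transport.
* **Corrections metadata**: per-role Bernoulli flags with probabilities
  0.91 (bladder), 0.13 (rectum), 0.68 (GTV), the clinically observed
  correction frequencies.
* **Seeding**: a master seed spawns per-patient and per-fraction child
  seeds; any single session is reproducible in isolation, and the whole
  cohort is bit-reproducible.

### Numerical choices

* The level-set perturbation needs a signed distance whose zero crossing is
  *sub-voxel* accurate: one-sided distance transforms quantize distances to
  lattice steps (≥ one voxel), which would make amplitudes below the voxel
  size provably inert. Near the interface the signed distance is therefore
  re-estimated from a Gaussian-smoothed occupancy (d ≈ (0.5 − o)·σ√(2π))
  and blended into the far-field transform.
* Mask rescaling (bladder filling) resamples the occupancy trilinearly and
  chooses the re-threshold by quantile so the achieved volume matches the
  target to within one voxel; a fixed 0.5 threshold leaves a few-percent
  digitization bias.
* Margin expansion, erosion and perturbation run on padded bounding boxes,
  not the full grid; the padding always covers the operation's reach, so
  the result is identical to the full-grid computation.
* Rasterization of planar contours uses the even-odd rule on voxel centers
  with a half-open edge convention (on-edge points belong to the
  minimum-coordinate side), making adjacent polygons tile without overlap
  and the result invariant under cyclic vertex reordering.
* Cohorts are streamed session by session; a full 17 × 20 cohort of mask
  volumes would occupy several GB if materialized.

### What the phantom does and does not show

Passing the pipeline's tests on this phantom demonstrates that the metrics,
statistics and tabulations are computed correctly and respond to controlled
discrepancies in the right direction and magnitude: measured median MDA
rises and DSC falls strictly with the true perturbation amplitude, a
systematically shrunken auto boost degrades boost-CTV coverage under the
auto-optimized dose while elective coverage is barely affected, and
coverage failures concentrate in the large-volume-difference strata when
the discrepancy amplitude is coupled to the volume change. It does *not*
validate any claim about real patients: the phantom has no CBCT image
content, no segmentation network, no deformable registration and no
optimizer — the auto-vs-clinical discrepancy distribution is a simulation
parameter, not an estimate of a clinical one.

Problem sizes used by the test suite: the full 17 × 20 cohort for the
amplitude-recovery sweep (amplitudes 0/1/3/6 mm, dose computed for the
zero-amplitude arm), reduced cohorts (≈ 2 × 2 to 6 × 6) for fixtures,
mechanism and determinism checks; the acceptance script runs the full
default 17 × 20 cohort with dose.

## Known limitations

* Surface distances are voxel-center based; sub-voxel surface localization
  (e.g. mesh-based HD) would differ by up to half a voxel diagonal.
* The spill definition mixes threshold levels for boost targets when the
  body level is elective (the default); the "own" body level avoids this at
  the cost of negative-spill-free guarantees only per level.
* The phantom's elective CTV omits lymph-node anatomy, its rectum is a
  tube, and dose falloff is isotropic — adequate for exercising the
  analysis, inadequate for clinical conclusions.
* OAR dose statistics (bowel, femoral heads), biological dose models and
  timing analyses are out of scope.
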