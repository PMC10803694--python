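# Methods

## Overview

The package quantifies regional lung deformation from a paired
inspiration/expiration volume per subject. The expiration volume is the
fixed frame; deformable registration yields a displacement field
`u: x ↦ u(x)` on the expiration grid such that `x + u(x)` is the
corresponding inspiration-space point. All downstream quantities derive
from the Jacobian determinant of that map.

## Jacobian stage chain

- **JAC** `= det(I + ∇u)` per voxel. Gradients are spacing-scaled central
  differences: 4th-order stencils in the array interior, 2nd-order within
  two voxels of the edge. On smooth fields at 2 mm spacing the truncation
  error inside the lung is ≲0.4%. Values are clipped below at `1e-6` and
  the clipped count is surfaced as a QC warning (a nonzero count signals a
  folding or badly regularized field).
- **JAC-N** `= JAC / (V_insp / V_exp)` with the volumes measured from the
  segmented lung masks (voxel count × voxel volume). By the change of
  variables, the lung mean of JAC equals the volume ratio, so the lung mean
  of JAC-N is ≈1: the normalization makes regional values relative to the
  whole-lung volume change. The division direction is fixed by the
  requirement that zero log means "deforms like the lung as a whole".
- **JAC-NL** `= ln JAC-N` (natural log). Positive = relative stretch,
  negative = relative shrinkage.
- **JAC-NLC**: JAC-NL resampled into a common anatomical space — the
  expiration grid of one control subject (lexicographically first control
  by default; recorded in provenance). The common-space transform is a
  mask-driven affine obtained by moment matching (centroid + per-axis
  second central moments), which is deterministic and, for the ellipsoidal
  anatomy of the synthetic cohort, optimal up to voxelization. Values are
  transported unchanged; multiplying by the affine determinant is available
  behind `rescale_by_determinant` but off by default, since the map
  represents a per-voxel log ratio, not a density.

### Endpoints

- **Jac-mean** `= |mean(JAC-NLC)|` over (common lung mask ∩ subject valid
  mask). The signed-mean-then-absolute-value form is the primary
  definition; a mean-of-absolute-values variant (`method="absolute"`) is
  provided because the signed mean lets balanced stretch/shrink cancel.
  Note that after normalization the signed mean is a Jensen-gap quantity:
  `mean(ln JAC-N) = mean(ln JAC) − ln mean(JAC) ≤ 0`, with magnitude
  growing with the spatial heterogeneity of deformation. Jac-mean is
  therefore a heterogeneity measure: a uniformly breathing lung scores 0
  regardless of how deeply it breathes.
- **Marked deformation area**: voxels with `JAC-NLC ≤ −cutoff`
  (default cutoff 0.15). The sign rule reads "below the cutoff" as marked
  *shrinkage*, because shrinkage is negative on the log scale and the
  highlighted areas are shrinkage areas; the literal reading
  (`JAC-NLC < +0.15`) is selectable (`sign_rule="literal"`) for
  sensitivity analysis.
- **Healthy deformation template**: the same segmentation applied to HAJ,
  the voxelwise control-group mean of JAC-NLC (coverage requires at least
  half the group contributing at a voxel, configurable). Only subjects
  labeled control contribute. **Dice** `= 2·TP/(2·TP + FN + FP)` compares a
  subject's marked area with the template; both-empty input is reported
  missing, not zero.

## Registration

Three interchangeable backends return the same contract (a dense mm
displacement field on the fixed grid, zero outside the ROI):

- `builtin`: multi-resolution diffeomorphic demons (SimpleITK). Defaults:
  3 levels, shrink factors 4/2/1, image-pyramid smoothing 4/2/0 mm,
  iterations 150/100/60, total-field Gaussian regularization σ = 1.5 mm.
  Images are cropped to the ROI bounding box (+4 voxels) first.
  Deterministic given inputs and configuration. Non-convergence (similarity
  not improving over the finest level) is flagged in the result, never
  silent. On default phantoms this recovers the true field with mean
  endpoint error ≈0.3 voxel (95th percentile ≈0.6 voxel).
- `external`: adapter for any tool that emits a dense warp on the fixed
  grid (callable `f(fixed, moving, roi) → (nx,ny,nz,3)` mm array).
- `oracle`: pass-through of a supplied ground-truth field, used to test
  everything downstream of registration exactly.

Mask warping (for IoU QC and mask transport) anti-aliases the binary mask
with a 0.8-voxel Gaussian, interpolates linearly and re-thresholds at 0.5;
this keeps subvoxel boundary fidelity (Dice ≈0.98 against the analytic
ground truth at 64³) where nearest-neighbor transport loses a full voxel.

## Synthetic cohort

The generator defines the study conditions for every test.

**Deformation model.** The expiration→inspiration map is
`T(x) = x + (A − I)(x − c) − α·S(r)·m(x)·(x − c)`, where `A` is a global
breathing expansion (`diag(1.17, 1.17, 1.22)` by default, ~12% healthy
volume excursion after the radial term), `c` the thorax center, `r` the
normalized elliptical radius with respect to the thoracic semi-axes
(42, 34, 46 mm), `S` a quintic (C²) smoothstep ramp switching the radial
contraction on outside `r = 0.55`, and `α = 0.15` the peak contraction
fraction. The attenuation factor
`m(x) = 1 − (1 − β)·basal(z)·H(r)` stiffens the peripheral shell
(`H` ramps up around `shell_fraction = 0.7`) preferentially in the
inferior half (`basal` falls from 1 to a 0.35 floor superiorly). `β = 1`
is the healthy pattern; `β → 0` the fully stiffened IPF-like pattern. The
displacement is C² everywhere; for `α ≤ 0.3` with default radii the map
is invertible (verified at construction by evaluating the Jacobian on the
grid — a non-invertible model is rejected).

Severity `s ∈ [0, 1]` maps to a subject model via `β = 1 − 0.95·s`,
`α ← α·(1 − 0.25·s)`, and a global-expansion reduction
`(A − I) ← (A − I)·(1 − 0.7·s)` (restrictive physiology: the volume
excursion falls from ~14% to ~6% across the severity range). Controls draw
`s ∈ [0, 0.12]`, IPF-like subjects `s ∈ [0.35, 0.95]`; anatomy (lung
radii) gets ±5% per-subject jitter. Because severity removes exactly the
peripheral contraction that creates deformation heterogeneity, Jac-mean
and Dice are strictly decreasing in severity by construction — the
parameter-recovery property the oracle tests check.

**Phantom rendering.** The expiration image is two ellipsoidal "lungs"
(intensity 60) inside a body ellipsoid (intensity 300) with smooth
multiplicative band-limited texture (Gaussian-filtered noise, σ = 2
voxels; 25% modulation in the lung, 10% in the body) so registration has
gradients to lock onto. The inspiration image is the expiration image
pulled back through `T⁻¹` (fixed-point inversion to 1e-6 mm), so the
forward registration target has the model displacement as exact ground
truth. Masks come from the analytic ellipsoid equations in each phase;
landmarks (two bilateral categories at one axial level on the body
surface: A mid-coronal, B anterior) are true correspondences under `T`.
Default grid 64³ at 2 mm spacing (desk scale); all sizes configurable.

**Clinical table.** Each severity-linked column is a monotone logistic
transform of `s` plus Gaussian noise with a stored per-column scale
(`noise_sd` multiplies all of them; 0 gives exact monotonicity): FVC%,
FEV1%, TLC%, DLco%, 6-MWD and vessel counts decrease with severity; CPI
(computed from the CPI formula, never drawn), MRC grade, SGRQ domains,
fibrosis extent and vessel tortuosity increase. The designed Spearman
correlation of any column is recoverable from the generator's own noise
model (`designed_spearman`). All randomness derives from a single seed;
identical seeds give byte-identical cohorts.

**What the phantoms do not emulate** — and hence what passing tests do
not show about real data: MRI contrast physics and artifacts, airway and
vessel structures, sliding motion at the pleura, lobar anatomy, real
segmentation difficulty (the threshold segmenter is adequate for bimodal
phantoms, not clinical images), and the magnitude of Jac-mean seen in
clinical cohorts: with a self-consistent normalization the synthetic
Jac-mean is a pure Jensen gap (~0.01–0.04 log units), so group
separation, monotonicity and correlation *structure* are meaningful
here, absolute values are not.

## Quality control and repeatability

- **IoU** between the registered inspiratory lung mask and the expiratory
  mask; **DA/DB**, the per-category mean Euclidean distances between
  landmarks transported through the field and their reference
  correspondences (per-subject mean over points, then cohort mean).
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures, computed from the ANOVA mean squares — rates test-retest
  agreement of IoU/DA/DB across two acquisitions; the two "raters" are the
  two repeated breath-hold acquisitions. Classification: null (≤0),
  slight, fair, moderate, good, very good (>0.80), almost perfect (>0.95).
  **Bland-Altman** limits are mean ± 1.96·SD of paired differences
  (n−1 SD).
- The two-phase study re-renders each subject twice (fresh texture, ±2%
  breathing-amplitude jitter) and re-runs the registration QC. Landmark
  observation adds a per-subject rater placement offset (sd 3 mm per axis,
  persistent across acquisitions) plus 0.3 mm per-acquisition jitter:
  without a persistent subject-level component, synthetic landmark
  distances are homogeneous registration error and the ICC is degenerate;
  with it, DA/DB sit at the few-mm scale with between-subject spread, the
  regime the repeatability analysis is designed for.

## Statistics

Two-group comparisons: unpaired t-test or Mann-Whitney U for quantitative
variables — `kind="auto"` screens both groups with Shapiro-Wilk at
α = 0.05 and always records which test it chose — and chi-square for
categorical tables. Spearman correlation (average ranks for ties,
two-sided p, ≥5 complete pairs) for all severity associations. The
severity report emits the three pairwise MRC-strata contrasts
(MRC 1 / 2 / ≥3, IPF-like subjects only) and the correlation table of both
endpoints against the clinical columns. p values are unadjusted by
default; Benjamini-Hochberg is available (`adjust="bh"`) and flagged in
the output. Missing data are handled complete-case per analysis.

## Pipeline, determinism and problem sizes

`analyze_cohort` orchestrates preprocess → registration → Jacobian chain →
common space → template (controls only) → per-subject Jac-mean/Dice → QC →
statistics. Per-subject failures are logged and skipped, never silently
absorbed; warnings (clipped voxels, non-convergence, skipped contrasts)
propagate to the manifest. The disk pipeline (`run_pipeline` /
`lungdeform run`) writes TSV/NIfTI/PNG/JSON outputs with a manifest
listing a SHA-256 per file; re-running with an identical configuration
reuses existing outputs, and two fresh runs from the same seed are
byte-identical.

Test and validation problem sizes are desk-scale by choice: single-subject
registration and Jacobian-oracle checks run at the default 64³/2 mm grid;
many-subject studies (replicate group-separation runs, the n = 80
correlation cohort, repeatability) run at 48³/2.67 mm, which spans the
same 128 mm field of view. Below 48³ the voxelization error of the
mask-derived volume ratio (~2%) is no longer small against the
Jensen-gap-scale Jac-mean signal, so coarser grids are not used for
cohort statistics.

## Numerical choices and degenerate inputs

- Resampled shapes round as `ceil(extent / spacing)`; images interpolate
  linearly, masks nearest-neighbor.
- "Dilated by ten pixels" is a Euclidean ball of radius 10 voxels on the
  isotropic grid (exact distance-transform implementation); the ROI radius
  is specified in mm and converted by the configured spacing.
- Log clipping at `1e-6`; empty masks, constant images, singular affines,
  zero-variance ICC tables and sub-minimum sample sizes are rejected with
  diagnostics rather than producing numbers.
- Both-empty overlap (Dice/IoU) is reported missing, never 0; projection
  lines without coverage are NaN, never 0.
- World coordinates: 0-based voxel indices, `world = origin + index ·
  spacing`, axis-aligned geometry only; all landmark and field quantities
  in mm.

## Known limitations

- The builtin demons backend matches intensities; cross-phase contrast
  changes (real lungs densify on expiration) would need histogram matching
  or a correlation metric — phantom phases share intensities by
  construction, so this is untested territory.
- The moment-matching affine has no rotational component; it is exact for
  the axis-aligned synthetic anatomy but would under-fit rotated subjects.
- The common space is one subject's anatomy; no groupwise template is
  built.
- Voxelwise group inference (statistical maps) and longitudinal change
  analysis are out of scope.
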