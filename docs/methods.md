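# Methods

This note records the models, parameter choices and numerical decisions
behind `octsp`, in the order the pipeline runs them.

## Synthetic eyes

The generator is the package's study population; everything downstream is
validated against it.

**Thickness model.** Separable in polar coordinates about the disc centre:
`T(r, θ) = radial(r) · profile(θ) · noise(x, y) · attenuation(r, θ)`.

* `profile(θ) = 60 + 100·[G(θ − θ_sup; 30°) + G(θ − θ_inf; 30°)]` µm — a
  temporal/nasal floor with two wrapped-Gaussian bundle humps. Calibrated
  at the 1.7 mm radius so a healthy circumpapillary mean lands near
  100 µm with bundle peaks near 160 µm.
* `radial(r) = clip((1.7 mm / r)^0.7, 0.35, 2.2)` — RNFL thickens toward
  the disc and decays toward the scan periphery.
* `noise` — a smooth multiplicative field (Gaussian-filtered white noise,
  correlation ≈ 2 % of the grid width, relative SD 4 %). Multiplicative so
  defects at full depth still zero the sector.
* Population bundle angles (65°, 295°) in the convention *0° temporal,
  counter-clockwise, superior hemifield (0°, 180°)*; per-eye jitter
  SD 7°. These two numbers are what atlas normalization must undo.
* Vessels: 8 random-walk curves leaving the disc margin near the bundles,
  dilated to ≈ 70 µm width; thickness × 0.65 and reflectivity × 0.75 under
  the shadow.
* Disc: radius 0.9 mm, thickness exactly 0 inside.

**Disease model.** A focal wedge defect is a multiplicative sector
attenuation `1 − depth·w(θ)·ρ(r)` with smooth 3° angular and 0.15 mm
radial tapers; diffuse loss is a global factor `1 − g`. Group severities
(chosen once as clinically plausible): suspects carry either one shallow
narrow defect (depth U(0.25, 0.45), width U(12°, 25°)) or borderline
thinning U(0.05, 0.12); glaucoma eyes carry one or two deep wide defects
(depth U(0.55, 0.95), width U(30°, 60°)) plus thinning U(0.05, 0.25).
Defects centre near a bundle (arcuate damage) and extend 1.8–3.0 mm from
the disc by default.

**What the generator does not emulate:** speckle, media opacity, motion
artifacts, real vessel branching topology, age effects, floor effects of
segmentation at severe damage. Passing tests therefore demonstrate
correctness of the *algorithms* under controlled truth, not clinical
performance on device data.

**Thin cubes.** `generate_eye(make_cube=True)` renders a two-interface
intensity cube (background 0.15, RNFL slab 0.85 modulated by
reflectivity, sub-RNFL 0.40; axial pitch 2 µm/voxel, metadata-overridable).
`segment_synthetic_cube` is a deliberately small threshold-crossing
segmenter for these cubes only (longest supra-threshold run per A-scan
after axial smoothing); A-scans with no detectable slab are QC-flagged.

## Bundle detection and angular normalization

Per sampling circle (default: every 0.18 mm from 0.3 mm outside the disc
to the largest inscribed circle), the angular profile is averaged over a
±0.09 mm radial band and smoothed by a 20° circular moving average.

Peak-finding on a broad hump is noise-limited: smooth map noise tilts the
argmax by several degrees. The detector therefore uses a squared-excess
intensity centroid (iterated, ±30° window) — far more stable than argmax —
with one correction: a monotone angular warp stretches one flank of a hump
and compresses the other, and any centroid is biased toward the wider
flank. The bias is estimated by fitting two split-width Gaussians plus
baseline to the radially pooled profile (asymmetry lightly penalized) and
applying the *same centroid operator to the fitted noiseless curve*; shape
parameters are much less noise-sensitive than a fitted location, so the
correction is robust on both warped and unwarped maps. Per-circle angles
are then the pooled anchor plus per-circle centroid differences (the
common bias cancels in the difference), smoothed across radii by a
slope-limited linear trend. Measured on the generator at default noise:
worst-case recovery error ≈ 4° (mean < 3°), and re-detection after
normalization lands within ≈ 1.5° of the reference angles.

The warp itself is piecewise linear in angle per circle, anchored at the
temporal (0°) and nasal (180°) horizontals and at the two bundle angles;
anchor angles interpolate linearly between listed radii and clamp beyond
them. Output pixels sample the input at `(r, φ_r(θ))` by bilinear
interpolation, so the identity warp reproduces the input exactly.
Disc-interior pixels are copied through. The disc centre is aligned by
construction of the polar frame (integer-pixel alignment suffices at
30 µm/px).

## Atlas and deviation

Pixelwise sample mean and (n−1)-SD over normalized healthy maps (default
cohort 46). Deviation of a normalized map: deficit
`max(0, (mean − n_sd·SD − T)/SD)` in SD units with `n_sd = 1` by default;
pixels with zero atlas SD (disc interior) are marked unevaluable rather
than producing infinities. Scan QC fails when the longest run of flagged
B-scans exceeds 8 % of the total or the cumulative count exceeds 12 %
(strict inequalities).

## Feature map

Vessel inpainting is separable bilinear interpolation: each vessel pixel
averages a row-wise and a column-wise linear interpolation between its
nearest non-vessel neighbours. This is exact on affine surfaces (the
defining property of bilinearity), idempotent, and leaves non-vessel
pixels untouched; positions with no flanking pair on either axis (map
border) fall back to the nearest non-vessel value. The combined scalar
channel is `(T/T_max)·(w_r + (1−w_r)·R)` with `w_r = 0.7`: multiplicative
so thickness ordering is preserved while low reflectivity (as in
glaucomatous RNFL) damps the intensity; the deviation stays a separate
channel consumed by the partition rule.

## Superpixel segmentation

Affinity between pixels within radius `r` (3 px at 200², 2 px on smaller
grids): `exp(−ΔI²/σ_I²)·exp(−d²/σ_X²)` with `σ_I = 0.1` on the [0, 1]
scalar channel and `σ_X = 4 px`. Disconnected regions are bridged by
nearest-pixel edges (weight 10⁻³) with a warning.

The k-way partition takes the k largest eigenvectors of the symmetrically
normalized affinity (dense solver below ~800 nodes, ARPACK with a fixed
start vector above — determinism matters), rescales them to generalized
eigenvectors of `(D−W)x = λDx`, and discretizes by degree-weighted
k-means (seeded k-means++). The ncut "stability" parameter maps to the
spatial-coherence weight of the discretization, `λ_c = 0.01/|stability|`:
the initial −0.1 gives flexible boundaries, the recursive −0.006 compact
ones. K-means labels are then decomposed into 8-connected components and
merged (smallest into its strongest 8-adjacent neighbour) or split
(largest across its widest coordinate) until exactly k connected segments
remain.

The recursive partition rule is in the README; numerical details:
`round()` is half-away-from-zero, fixed for reproducibility; a segment
below `2·S_min` never splits; `σ = 0` disables the thick branch; the split
count is capped at `⌊S/(2·S_min)⌋`; refinement iterates to a fixed point
(max 10 passes, warning on non-convergence). `S_min = 50 px` on the
200 × 200 grid, scaled by pixel-area ratio elsewhere.

One deliberate design choice: the rule's global statistics (μ, σ, T_max)
come from the normative atlas mean map when one is available, not from the
eye under test. With eye-relative statistics, deeper damage lowers the
eye's own mean and flips unrelated near-mean segments from the thin to
the thick branch, so total superpixel counts can *decrease* with defect
depth; a fixed population reference keeps the branch thresholds stable
and makes the pathological response monotone. Without an atlas the
own-map statistics are used.

## Features

9 counts + 16 moments + 40 histogram bins + 3 global averages = 68.
Thickness-range counts use segment mean thickness (segments are
near-homogeneous by construction); interval convention is half-open
[lo, hi) for the printed ranges, strict inequalities for the
`T_min < size < T1` and `size > T2` subgroup definitions. Moments are
mean, (n−1)-SD, and standardized third/fourth central moments (m₃/s³,
m₄/s⁴ with population s — a normal sample gives kurtosis ≈ 3); empty or
single-member subgroups yield zeros and a flag rather than NaNs.
Histograms use 20 equal-width bins over [0, 165] µm for thickness and
[0, 600] px (area-scaled) for size, normalized to segment-count fractions;
out-of-range values clip into the end bin with a warning. Global
averages: mean thickness interpolated at 256 points on the 3.4 mm circle,
over the whole scan, and over the scan excluding the disc.

## Classification and evaluation

LogitBoost with regression stumps: working response
`z = (y* − p)/(p(1−p))` clipped to |z| ≤ 4, weights `p(1−p)` floored at
2·10⁻⁶, stump thresholds at midpoints of sorted distinct values with ties
broken toward the smaller threshold, update `F ← F + ν·f`,
`p = 1/(1+e^{−2F})`. Defaults M = 100 iterations, ν = 0.1 — stable on
cohorts of ~100 eyes; both configurable. Scores are the additive stump
sum, negative→healthy, positive→disease.

Evaluation: stratified 10-fold cross-validation (optionally grouped by
subject so both eyes of one subject share a fold; a seeded one-eye-per-
subject sampler is provided for duplicate-subject cohorts); AUC by
Mann–Whitney with ties at ½; DeLong variance from placement values;
paired-AUC comparison by DeLong z-test with 95 % CI (equivalent to the
leave-one-out jackknife up to a small finite-sample factor). Sensitivity
at 85 % specificity takes the maximum sensitivity among operating points
with specificity ≥ 0.85. Three two-class tasks mirror the clinical
questions: healthy vs suspect, healthy vs glaucoma, healthy vs all
disease. The cpRNFL baseline scores eyes by (negated) mean and quadrant
means on the 3.4 mm circle, with quadrants as half-open 90° bins centred
on the temporal/superior/nasal/inferior axes.

## Problem sizes

Cohort-scale experiments (atlas building, the 40/60/90 cross-validation
study, the acceptance script) run on a 64 × 64 grid covering the same
6 × 6 mm field (93.75 µm/px), with all pixel-count parameters scaled by
area; single-map analyses and the calibration/recovery checks run at the
full 200 × 200 resolution. This keeps a ~240-eye study to a few minutes
on one CPU while exercising every stage at full resolution at least once.

## Known limitations

* The recursive partition rule saturates thin regions down to near the
  minimum segment size, so absolute superpixel counts are higher than
  one would see with a gentler rule; group *ordering* (healthy < suspect
  < glaucoma) is preserved and is what the count features encode.
* Bundle detection assumes one dominant hump per hemifield; split or
  double bundles would need a richer model.
* The DeLong/jackknife agreement holds to ~5 % on balanced 10+10 paired
  designs; heavily unbalanced tiny samples differ by a known
  finite-sample factor.
* Synthetic-data realism limits are listed above; none of the reported
  AUCs should be read as clinical performance.
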