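# Methods

This note documents the models, parameter choices and numerical decisions
behind `perfrad`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic experiments can and
cannot show.

## Region models and thresholds

Three tissue compartments are delineated per subject on co-registered
volumes indexed `(x, y, z)` with x the left–right axis:

* **Ischemic** — Tmax > 6 s on the DSC-PWI time-to-maximum map. The 6 s
  cut is the standard hypoperfusion criterion.
* **Infarct** — ADC < 620×10⁻⁶ mm²/s, with ADC computed voxelwise from a
  DWI pair as ADC = −(1/b)·ln(S_b=1000 / S_b=0). Voxels where either
  signal is ≤ 0 are flagged invalid (NaN) and can never enter the mask.
* **Hypoxic** — grid units of the affected hemisphere whose venous oxygen
  saturation falls below 0.7 (details below).

All thresholds are **strict** inequalities; a voxel exactly at 6 s,
620×10⁻⁶ mm²/s, 90 or 300 ppb, or an SvO₂ of exactly 0.7, is excluded.
This is the reading of the thresholds as printed, and it makes boundary
behaviour testable (the ADC boundary case is asserted exactly).

### The SvO₂ grid procedure

Physically, the susceptibility of a draining vein relative to
surrounding tissue follows Δχ_vein−tissue = Δχ_do · (1 − SvO₂) · Hct with
Δχ_do = 0.18 ppm and Hct the venous hematocrit. Both constants are
uncertain per subject, so the implementation uses only the **ratio**
form, in which they cancel: with the contralateral hemisphere assumed
healthy at SvO₂_ref = 0.7,

    ΔSvO₂ = −(1 − SvO₂_ref) · (X̄_ref − X̄_roi) / X̄_ref
    SvO₂  = SvO₂_ref − ΔSvO₂.

`SvO2Params` still carries Δχ_do and Hct as documented constants.

Steps and choices:

* **Upright alignment.** The brain-mask centroid is shifted (integer
  voxels) to the in-plane volume centre; the midsagittal deviation angle
  is estimated by minimizing the voxel mismatch between the mask and its
  left–right reflection over ±20° in 0.25° steps (ties broken toward 0°).
  Angle and shift are recorded so masks can be mapped back to native
  space. Exhaustive search is cheap at these volume sizes and has no
  local-minimum failure mode.
* **Midline** = the vertical plane through the aligned brain-mask
  centroid. The affected hemisphere is the one containing the ischemic
  mask centroid (lesions are unilateral by construction).
* **Grid.** Per axial slice, each hemisphere's bounding box is split into
  a 10×10 in-plane grid (one unit per slice in z). Remainder voxels
  widen the **lateral-most** interval of each hemisphere and the last y
  interval; putting the x remainder at the lateral end keeps mirrored
  units congruent, so unit (i, j) — with i counted medial→lateral — is
  the exact geometric mirror of its contralateral partner on a symmetric
  brain. The grid spans the per-slice hemisphere bounding box (not the
  half-volume); this choice is surfaced in the configuration.
* **Vein extraction.** Vein voxels satisfy 90 ppb < χ < 300 ppb (lower
  bound extracts draining veins, upper bound rejects outliers; both
  strict). Per-unit mean vein susceptibility is computed after sorting
  the values, which makes the mean independent of voxel visit order —
  mirrored units holding identical values then agree bitwise, so a
  symmetric noise-free phantom produces SvO₂ ≡ 0.7 exactly and an empty
  hypoxic mask, as it should.
* **Degenerate units.** Units with no vein voxels, a missing mirror, or a
  zero reference mean get no SvO₂ (NaN), never ±∞, and are excluded from
  the hypoxic mask.
* **Unit granularity.** The hypoxic mask is the union of flagged units'
  extents ∩ brain mask (unit-granular, not voxel-granular).
* SvO₂ values are **not clipped** to [0, 1]; out-of-range values are
  reported as computed and compared to 0.7, keeping the raw formula
  output auditable.

Note a structural property the strict 0.7 rule implies: the reference
point of a unit equal to its mirror is exactly 0.7, so *any* negative
susceptibility fluctuation pushes a unit below threshold. On noisy data
roughly half of all symmetric vein-bearing units are flagged; the
analysis scripts quantify this. It is a property of the method being
reproduced, not an implementation artifact.

## Radiomics

Feature definitions follow the common IBSI-style formulary (log base 2
throughout), implemented from first principles and checked bit-exactly
against brute-force enumerations in the test suite.

* **Discretization**: fixed bin width, level = ⌊(x − min_mask)/w⌋ + 1,
  default w = 25 map units (the de-facto ecosystem default; configurable,
  including a fixed-bin-count scheme under which features are invariant
  to affine intensity rescaling).
* **Matrices**: GLCM — symmetric counts at Chebyshev distance 1 over the
  13 unique 3D directions; GLRLM — run counts per direction; GLSZM —
  26-connected zones; GLDM — dependence counts in the 26-neighbourhood
  (α = 0); NGTDM — per-level counts n_i and summed deviations s_i from
  the in-mask neighbourhood mean (voxels with no in-mask neighbour are
  excluded from n_i).
* **Aggregation**: GLCM/GLRLM features are computed per direction and
  averaged (the most common convention).
* **Feature sets**: 18 first-order, 23 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM,
  5 NGTDM features. Degenerate inputs return documented constants
  instead of NaN: single gray level → correlation 1, information
  measures 0; zero NGTDM deviations → coarseness capped at 10⁶,
  contrast/busyness/strength 0; single voxel → variance/skewness/
  kurtosis 0. Every emitted value is asserted finite.
* **Filter bank** (18 images per map): original; Laplacian of Gaussian at
  physical scales σ ∈ {1,…,5} mm converted through the voxel spacing;
  one-level separable 3D wavelet (coif1), all eight subbands
  reconstructed to image size (their sum reproduces the input, which the
  tests exploit); and four monotone intensity remaps (square, square
  root, logarithm, exponential) applied to the min–max-normalized
  intensity and rescaled back to the original range — monotone,
  constant-preserving, and commensurate with the fixed-bin-width
  discretization across filters.
* Extraction operates on native grids (synthetic grids are isotropic per
  axis by construction); shape/morphology features are out of scope.
* Regions below 10 voxels (configurable) flag the subject; features are
  never fabricated.

Feature names follow `region__map__filter__class__feature`, e.g.
`ischemic__Tmax__log-sigma-3__glszm__ZoneEntropy`.

## Selection

* Standardization F* = (F − F̄)/(F_max − F_min) with statistics fitted on
  **training rows only** and applied to all rows (no leakage; a flag in
  the calling code can reproduce whole-cohort fitting, but train-only is
  the default because the alternative leaks the test distribution).
  Zero-range features map to 0 with a warning.
* Two-sided Student's (equal-variance) two-sample t-test per feature,
  matching SPSS's "independent sample t-test"; Welch is available via a
  flag. Keep p < α = 0.05 strictly; p = α drops. No multiple-testing
  correction, deliberately mirroring the emulated design.
* Lasso: cross-validated **least-squares** L1 regression of the 0/1 label
  (the behaviour of scikit-learn's `LassoCV`), not logistic L1 —
  fidelity to the stated implementation. 5 folds (shuffled, seeded), 100
  log-spaced penalties, retain |w| > 0. Selection runs separately per
  perfusion map within each region, and the retained sets are
  concatenated; an empty selection is a reported outcome, not an error.
* The 14 experimental groups are the 7 region combinations ×
  {radiomics, parameters}; parameter groups carry 4 regional means per
  region and are standardized the same way before classification.

## Evaluation

* Stratified 7:3 split with a fixed rounding convention: floor the train
  count for the good class, ceil for the poor class — 45+45 splits into
  63 train (31 good / 32 poor) and 27 test (14 good / 13 poor).
* Panel: SVC, MLP, random forest, AdaBoost, logistic regression, Gaussian
  NB, at library defaults with fixed seeds (MLP and LR get raised
  iteration caps purely for convergence; all hyperparameters are exposed).
  The positive class is poor function. Scores are predicted
  probabilities where available, decision values otherwise; AUC is the
  Mann–Whitney rank statistic with ties counted half, verified against
  an all-pairs oracle. A single classifier failing on a degenerate
  table is recorded per cell, not fatal to the matrix.

## The synthetic cohort generator

The generator's defaults are the emulated study conditions: 45 good + 45
poor subjects, and per-(region, map, class) targets for the mean and SD
of subject-level regional means taken from the published two-class
cohort statistics (e.g. ischemic Tmax 6.24 ± 4.49 s good vs 12.18 ± 6.28 s
poor). Geometry, by contrast, is a modeling choice — no lesion-shape
statistics are published — and is kept as simple as possible while still
yielding non-trivial texture:

* 48×48×14 voxel volumes at 4×4×5 mm (a deliberately coarse grid chosen
  for the simulation studies; all operators are resolution-agnostic),
  ellipsoidal brain, ellipsoidal unilateral ischemic lesion (semi-axes
  4–7 voxels) with a concentric infarct core at 0.55× its radii.
* Per-subject region values are drawn from the configured class normal;
  because maps are floored at zero, the draw uses a truncation-corrected
  mean (solved with a root finder) so the realized across-subject means
  stay on target. The infarct core gets its own value and the ischemic
  rim is compensated so the whole-region mean equals its draw exactly;
  hypoxic units (disjoint from the lesion) get theirs. Lesion-to-
  background transitions taper with a Gaussian profile applied **outside**
  the truth masks, so regional means are unaffected. Voxel noise is
  spatially correlated Gaussian, truncated at physical floors.
* The DWI pair is synthesized by inverting the ADC relation from a
  ground-truth ADC field that is clipped strictly below 620×10⁻⁶ mm²/s
  inside the core and strictly above outside — so recomputing ADC and
  thresholding recovers the infarct mask voxelwise at any noise level.
* The susceptibility map holds random-walk vein tubes (≈1 voxel radius,
  χ ~ U(120, 200) ppb) generated in one hemisphere and mirrored exactly;
  designated hypoxic units in the affected hemisphere get +80 ppb on
  their vein voxels. With susceptibility noise off, the SvO₂ procedure
  recovers exactly those units; the default adds 5 ppb vein noise for
  realism.
* Per-subject seeds are master_seed + index: cohorts are bit-reproducible
  and subjects distinct.

**What the phantoms do not emulate** — and hence what passing tests do
not show about clinical data: MR acquisition physics and deconvolution,
registration error (volumes are generated co-registered), realistic
lesion morphology and mass effect, partial-volume effects at clinical
resolution, vascular anatomy beyond random tubes, and any correlation
structure between maps beyond shared geometry. The planted-effect
experiments demonstrate that the pipeline recovers class structure it is
given at published effect sizes; they cannot certify clinical accuracy.

One tension is worth making explicit: clinically, the ischemic region is
*defined* by Tmax > 6 s, so every real subject's regional mean exceeds
6 s, yet published across-subject statistics (6.24 ± 4.49 s in the good
class) imply many subjects near or below the cut. The phantom resolves
this by making the lesion geometric ground truth with the published
values as distributional targets: good-class subjects genuinely straddle
the threshold, and threshold segmentation then behaves exactly as it
would on vendor-thresholded maps. Classification experiments therefore
extract features from the ground-truth masks (standing in for the
vendor-provided masks treated as inputs clinically); exact
threshold-recovery is asserted on noise-free, well-separated
configurations where it is meaningful.

## Simulation sizes

The multi-seed experiments use 90-subject cohorts (the emulated cohort
size) with the original-image filter bank and all six feature classes —
the full 18-filter bank is exercised separately on single subjects. The
planted-effect acceptance check uses 10 seeds (20 for the mis-localized
control comparison) and statistical-fidelity checks use 200 subjects per
class; these sizes give stable medians and standard errors while keeping
a full run in the minutes range on one CPU.

## Known limitations

* The SvO₂ procedure assumes symmetric vein anatomy; units whose mirror
  lacks veins produce no estimate, and the strict 0.7 cut over-calls
  hypoxia under noise (quantified in `analysis/02_segment_regions.py`).
* `LassoCV` on 0/1 labels is a linear-probability model; it mirrors the
  emulated implementation but is not a calibrated classifier.
* Best-classifier-by-test-AUC (used for reporting) is optimistically
  biased on 27 test subjects; the permutation baseline in the acceptance
  experiment quantifies the null spread.
* Single shared split per experiment matrix (by design of the emulated
  study); no nested cross-validation or hyperparameter search.
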