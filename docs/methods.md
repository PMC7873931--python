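# Methods

## The measurement problem

Slaughter-line camera systems grade footpad dermatitis (FPD) from 2-D RGB
pictures of single suspended feet against a dark background.  The standard
five-point score uses only the metatarsal pad: the relative area of
brownish alteration on the pad maps to scores 0–4.  This package models the
whole chain — image, masks, relative areas, categorical scores, and the
statistics used to relate digital-pad involvement to the standard score —
so that every stage can be validated against exact ground truth.

## Synthetic feet

No public image corpus exists for this setting, so the generator *is* the
data source, and its defaults define the study conditions.

**Geometry.**  A foot is a metatarsal pad drawn as a superellipse
(exponent 2.5; semi-axes 0.19 H × 0.30 W of a default 260 × 200 px frame)
plus digits 2–4 hanging image-down, each a chain of
`n_segments_per_digit = 3` elliptical phalanx pads (semi-axes
0.062 H × 0.040 W, center spacing 1.7 lengths) whose overlap produces a
constricted waist at each joint.  Digit 1 is never drawn: a suspended foot
does not present it to the camera.  The turkey-specific phalanx count is
not part of any rubric; 3 segments is a configurable default, not an
anatomical claim.  The background is dark gray (15), skin a light
skin tone (210, 170, 135); validation enforces a ≥ 40-intensity margin
between them.

**Lesions.**  Brownish discolorations are grown pixel-by-pixel inside the
target region (pad, or one phalanx segment) by randomized-Prim (Eden)
growth until the requested pixel count — `round(fraction × region area)` —
is reached, so ground-truth relative areas are exact to one pixel.  Colors
interpolate a light-to-dark brown range; per-pixel Gaussian noise
(σ = 2 intensity levels) is added to both feet.

**Swelling.**  A swollen digit's segment chain is scaled isotropically by
√factor in both axes (area × factor), anchored at the pad attachment.  The
paired reference foot shares the base geometry, carries no lesions or
swelling, and is mirrored left–right, as a contralateral foot would be.

**Cohorts.**  A stratified cohort draws `n_per_level = 100` feet per
standard level (levels 0–4, 500 feet total) across `n_flocks = 16` flocks,
in pseudorandomized order, with the evaluated foot per pair on the
preferred (left) side.  Pad-lesion fractions are drawn uniformly inside
each level's ratio interval — 0; (0, 0.10); [0.10, 0.25]; (0.25, 0.50];
(0.50, 0.95] — then realized in whole pixels chosen so the quantized
fraction still scores that level; level 4 is capped at 0.95 to keep a
visible healthy rim.  Digital involvement follows level-conditional
tables (probability of 0–3 affected digits, lesion grade, swelling grade)
in which grade 1 dominates and digit 4 is least affected; a
`digit_concordance` knob interpolates toward the level-independent
average, giving cohorts whose digital lesions are independent of the pad
by construction (a generation-side oracle for the correlation analyses).
An alternative `digit_model="latent"` drives all six digit variables from
one per-foot standard-normal severity with loading 0.7 — exactly the
one-factor latent-normal structure the polychoric-PCA digital score
assumes — and stores the severity for recovery checks.  Grade-to-fraction
realization samples from intervals kept clear of the rubric boundaries
(punctual 0.02–0.045; intermediate 0.08–0.45; large 0.55–0.92; slight
swelling 1.18–1.32, distinct 1.40–1.60) so that one-pixel quantization
cannot flip a generated grade.

**What the generator does not emulate** — and hence what passing tests do
not show about abattoir photographs: shadows, shackles, blood and dirt,
feather remnants, perspective and pose variation, out-of-focus frames,
toenails, and hematoma coloration (hematomas enter the rubric only as an
input flag).  Results on synthetic cohorts validate the *logic* of the
chain, not the robustness of any color threshold on real material.

## Segmentation

Design commitments, chosen so each step uses only cues available in the
slaughter-line setting:

* **Foot**: luminance threshold (configurable; auto mode estimates the
  background from the image border as median + 15 % of the
  border-to-maximum contrast — deliberately below even dark-brown lesions,
  which must stay inside the foot), largest connected component, holes
  filled.
* **Pad vs. digits**: a morphological opening with a disk of radius 13 px
  erases the narrow digits but preserves the wide pad; the three largest
  residual components are the digit branches, ordered left-to-right as
  digits 2, 3, 4 (a flip flag handles the opposite orientation).  The
  radius must exceed the half-width of a maximally swollen digit (~10 px
  at factor 1.6) and stay below the pad half-axis (~49 px).  A width-flare
  trim reassigns branch rows wider than 1.8 × the branch median to the pad,
  implementing the "start of the curvature" boundary.
* **Segments**: local minima of the digit's row-width profile (smoothed
  with a 5-row boxcar) mark the joint constrictions; if fewer than
  `n_segments − 1` minima are found the digit is divided into equal-length
  row bins.
* **Lesions**: pixels inside the foot whose HSV hue lies in [0, 0.18] and
  value below 0.72 (brown: skin-like hue, darker value); connected
  speckles under 5 px are discarded.  The defaults are tuned to the
  generator's palette and fully exposed in `SegConfig` — no numeric color
  thresholds exist for the commercial systems.

Mask invariants (pad ⊆ foot, digits ⊆ foot, pad ∩ digit = ∅, segments
partition each digit, lesions ⊆ foot) are validated after every full run.

## Morphometry

Areas are raw pixel counts; all six parameters are dimensionless, so no
physical calibration is needed.  `FULL` is computed as
`FP/RA1 + DP/RA1` so the additivity identity holds to the last bit.
`DP/RA2` relates disjoint regions and is deliberately not clamped at 1.
When a connected discoloration straddles the pad/digit boundary with a
mere spill on one side (≤ 20 px), the whole lesion is counted on its
majority side: a boundary estimate a few pixels off must not turn an
intact pad into score 1, since the 0 → 1 rubric boundary is infinitely
sharp.  Substantially straddling lesions are split by plain intersection
— a fixed spill tolerance bounds the attribution error of any boundary
estimate to a few tens of pixels — and the pad count is capped at the pad
area.  On exact ground-truth masks the rule reduces to intersection
counting whenever lesions keep more than 20 px off the boundary.

## Scoring

Bin edges follow the printed rubric wording: score 1 is "< 10 %", so 10 %
itself belongs to score 2, 25 % to score 2, 50 % to score 3.  "Punctual"
is quantified as a segment fraction ≤ 0.05 (configurable; the rubric never
quantifies it).  The per-digit decision table resolves the overlapping
printed wording of grades 2/3 by lesion count and punctuality: grade 2 is
one intermediate segment or punctual marks on more than two segments;
grade 3 is one segment at ≥ 50 % or several intermediate segments; grade 4
is two segments at ≥ 50 % or a lesion exceeding a phalanx.  The table is
total and monotone under pointwise increase of the fractions
(property-tested).  Swelling thresholds (area ratio ≥ 1.15 slight,
≥ 1.35 distinct) are invented operational defaults for a grade that is
visual in practice; they are configuration, not claims.  A missing
contralateral reference withholds the swelling grade (recorded as missing,
never 0).

## Statistics

**Krippendorff's alpha** is computed from the coincidence matrix with
per-item pairability (no imputation).  The ordinal difference squares the
cumulative-marginal distance between categories; the interval difference
squares value differences.  `D_e = 0` (no variation) raises an explicit
"alpha undefined" error.  Landis–Koch labels close each band at its
printed boundaries; values in the printed gaps (e.g. 0.805) join the lower
band.

**Polychoric correlation** uses the two-step estimator: thresholds from
inverse-normal cumulative marginals, then a bounded scalar likelihood
maximization of the bivariate-normal cell probabilities over
ρ ∈ (−1, 1) (tolerance 1e-6); boundary solutions are clamped to
±(1 − 1e-6) with a warning.  The matrix assembly repairs indefiniteness by
eigenvalue clipping.  Simulation at the study size (5 equiprobable
categories, n = 2000, 50 replicates) recovers ρ ∈ {0.3, 0.6, 0.9} with
mean absolute error < 0.02 and |bias| < 0.01.

**Digital score.**  Principal-axis factoring with squared-multiple-
correlation priors: the retained factor count is fixed from the first-pass
eigenvalues of the SMC-reduced matrix (minimum eigenvalue 1), after which
communalities are iterated to 1e-6 (max 100 iterations; Heywood cases
clamped with a warning).  Varimax applies when ≥ 2 factors are retained
(a single factor is rotation-invariant); each factor is oriented so its
loading sum is positive, since the score's sign is conventional.
Regression scoring coefficients `R⁻¹Λ` applied to standardized
numeric-coded grades give the per-foot digital score.  Standardizing the
ordinal codes before scoring is a committed choice.

**Friedman test** in rank-transform form: mid-ranks within each foot,
then the two-way ANOVA F for the digit effect with
df = (k−1, (n−1)(k−1)); the tie-corrected chi-square is reported
alongside.  Feet with missing digit values are dropped and counted.
Under the exchangeable null (100 feet × 3 digits, 1000 replicates) the
empirical size at nominal 0.05 is ≈ 0.05.

**Level comparisons** are fixed-effects one-way ANOVA plus Tukey-Kramer
studentized-range pairwise tests (statsmodels); mixed models with random
flock effects are out of scope, flock being available as a stratification
label only.

## Problem sizes

The bundled drivers and checks use: 500-foot cohorts (100 per level) for
score recovery and correlation structure, 100 feet for morphometric error,
400/100 items for the simulated two-observer reliability table, n = 2000
for latent-recovery simulations, and 1000 replicates for the Friedman
size check.  All are regenerated from seeds at run time; nothing is
stored.

## Known limitations

* The commercial systems' algorithms are undisclosed; this segmentation is
  a faithful implementation of the publicly described cues (background
  contrast, interdigital spaces, discoloration), not of any proprietary
  code.  Some deployed systems reportedly approximate the metatarsal pad
  by a fitted circle; here the segmented region itself is used.
* Observer-reliability values depend entirely on the simulated error
  model; they demonstrate the estimator, not human performance.
* Hematoma detection is not attempted (no operational color definition);
  the flag is an input.
* With complete 500 × 3 grids the Friedman denominator df is
  (n−1)(k−1) = 998; reported dfs always derive from the analyzed grid.
* `rel_met` carries a small systematic offset (~0.005) because the
  opening-based boundary sits slightly into the digits; it cancels in the
  lesion ratios, which are accurate to ~0.01 absolute.
* All cohort feet share one base geometry (only lesions and swelling
  vary), so absolute pixel counts of the reference areas are nearly
  constant across feet.  Interval-level agreement on such counts is then
  dominated by measurement noise rather than between-foot variation and
  can be near zero even for precise observers — real feet vary in size,
  which is precisely what makes those reliability values high in
  practice.
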