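# Methods

## Problem and pipeline

Catheter-administered intraperitoneal (IP) chemotherapy only reaches the
tissue it physically touches. CT peritoneography — scanning after injecting
diluted iodinated contrast through the IP catheter — shows the compartment(s)
actually available to the infusate. `periquant` quantifies those compartments
(volume in cm³, surface area in cm², SA:V in cm⁻¹) from a semi-automated
segmentation, and provides the statistical pipeline that relates the metrics
to overall survival and to posttreatment renal function.

The pipeline is: load a CT volume → draw a rectangular ROI on one axial slice
enclosing all contrast → threshold-plus-component segmentation of that slice →
iterative propagation to neighboring slices → optional manual add/remove
edits → voxel-based quantification → cohort statistics.

## Segmentation model

Contrast is recognized purely by density: a voxel is a *candidate* when its
intensity lies in a two-sided band `[hu_low, hu_high]` (default **[100, 600]**
on the Hounsfield-like scale). Diluted iohexol is far brighter than soft
tissue (~0–80) but well below cortical bone (~1000); the upper bound is what
keeps bone out. On the seed slice, candidates inside the ROI are grouped into
2D connected components (8-connectivity by default — fluid films touch
diagonally), components smaller than `min_component_voxels` (default 10) are
discarded as noise, and labels are assigned 1..K by descending size with a
deterministic coordinate tie-break.

Propagation is a fixpoint over a slice worklist. A slice is (re)examined
whenever an accepted neighbor changes, so a compartment whose parts only
connect through distant slices (a U-shape in z) is still fully recovered.
A candidate 2D component on slice *z* is accepted when its pixelwise overlap
with the nearest non-empty accepted slice within `max_slice_gap + 1` slices is
at least `overlap_fraction` (default **0.2**) of the smaller of the two areas;
a component with *zero* direct overlap is still admitted when it is diagonally
contiguous in 3D (under `connectivity_3d`, default 26) with an adjacent
accepted slice — this is how newly appearing lobes of a connected compartment
enter. `max_slice_gap` defaults to **0** (strict contiguity): contrast pools
are connected fluid, and a gap signals a separate structure that deserves its
own seed. Final labels are 3D connected components of all accepted voxels,
renumbered by descending voxel count.

Two limiting behaviors anchor correctness: (i) with a vanishing overlap
requirement and unlimited gap tolerance, the accepted set equals the 3D
connected components of the threshold band that intersect the seed — verified
against an independent 3D labeling on small random volumes; (ii) on noiseless
phantoms the result is identical regardless of which slice of a connected
compartment is seeded.

Manual corrections (`apply_edits`) zero removed voxels; added voxels adopt the
majority label among their 26-neighbors (labels grow outward into large
additions), and isolated additions become new compartments. Labels are then
renumbered contiguously.

## Quantification

The definitions are voxel-literal, not mesh-based:

- **Volume** = voxel count × dx × dy × dz.
- **Surface area** = Σ over compartment-voxel faces whose neighbor is
  background, a different label, or outside the grid, each face weighted by
  the product of the two spacings spanning it (dy·dz for x-facing faces,
  etc.). Grid-boundary faces count as exposed: a compartment clipped at the
  scan edge exposes the cut face (pad the volume if undesired).

Per-label areas count faces toward other labels on both sides; the *total*
surface area is computed on the union (label > 0) mask so internal interfaces
between touching compartments are not double-counted. The total therefore
equals the per-label sum exactly when no two labels touch.

The voxel-face sum of a digitized smooth surface does **not** converge to the
Euclidean area but to the ℓ1 (staircase) perimeter — for a sphere, 1.5 × 4πr².
This is intrinsic to the definition, and the ratio 1.5 is itself a useful
check: the measured digitized-sphere area at 0.05 cm spacing sits within 3 %
of 1.5 × 4πr². Volume, by contrast, converges to the continuous volume as
spacing shrinks (monotone error decrease across 0.2 / 0.1 / 0.05 cm in the
tests). No smoothed estimator is offered as a default anywhere.

Patients scanned twice contribute the arithmetic mean of the two scans' total
volume and surface area (`average_duplicate_scans`).

## Phantoms

`PhantomSpec` renders boxes, spheres, ellipsoids and thin sheets into a
soft-tissue background (40), at contrast intensity 250, with optional
bone-like distractors (1000), Gaussian blur (a partial-volume surrogate) and
seeded Gaussian noise applied last. Ground truth is **voxel-center
inclusion**, which makes the truth mask exact and the generator fully
deterministic for a fixed seed. Default spacing (0.07, 0.07, 0.5) cm mimics
clinical CT anisotropy; convergence tests use fine isotropic grids. Overlapping
shapes are rejected rather than resolved.

What the phantoms do *not* emulate: beam hardening, streak artifacts,
respiratory motion, anatomy-shaped compartments, or contrast-concentration
gradients. Passing phantom tests therefore demonstrates algorithmic
correctness of segmentation and quantification, not clinical robustness on
real scans — which is also why the workflow retains the radiologist edit step.

`loculation_contrast_pair` builds an equal-volume sphere (loculated pocket:
minimal SA:V) and 3-voxel-thick sheet (free-flowing film), with sheet edges
snapped to voxel boundaries so the digitized volumes agree within 1 %. The
sheet's SA:V exceeds the sphere's severalfold — the geometric rationale for
treating a high SA:V compartment as favorable for IP drug distribution.

## Clinical formulas

- Mosteller BSA: √(height_cm · weight_kg / 3600) m².
- Cockcroft–Gault clearance: (140 − age) · weight / (72 · SCr), × 0.85 for
  women, using actual body weight (the simplest literal reading; ideal-weight
  variants are out of scope).
- Plasma AUC: trapezoidal rule over the sampled span only. Samples at 10, 30
  and 60 min integrate 10→60; extrapolation to t = 0 (prepending a zero
  concentration) exists behind an explicit flag and is off by default, since
  assuming zero drug at the start of perfusion is a modeling choice, not data.

## Cohort statistics

- **Kaplan–Meier**: lifelines product-limit estimator; median = earliest time
  with S(t) ≤ 0.5; median CI from the log-minus-log–transformed survival
  band (Brookmeyer–Crowley style). No events → flat curve, median flagged
  undefined rather than an error.
- **Group comparison**: Welch t-test by default (pooled variance optional);
  robust to the unequal group sizes and variances typical of
  residual-disease splits.
- **Cox models**: statsmodels `PHReg`, **Breslow** tie handling by default
  with Efron as an option. Wald CIs and p-values per covariate; global p by
  likelihood ratio against the all-zero model. Constant covariates and
  event-free data are rejected; non-finite estimates (e.g. complete
  separation) raise. The partial likelihood is cross-checked in the tests
  against a hand-written brute-force risk-set summation at the fitted and the
  null coefficients (agreement to 1e-8 on tied small datasets).
- **Screen → multivariate**: compartment volume and surface area always enter
  the multivariate model; any other candidate enters iff its univariate
  p < 0.1. The forced inclusion is configurable (`force_include=()`) because
  a screening-only variant is equally defensible.
- **Per-SD hazard ratios**: exp(β·SD) with CI exp((β ± 1.96 SE)·SD). For
  covariates spanning thousands of cm² or cm³ the per-unit HR rounds to
  1.000 while the per-SD HR is far from 1; the per-SD scale is the legible
  one. Note that per-SD HRs computed from *rounded* per-unit HRs are
  unreliable — exp(−0.001 × 1158.5) ≈ 0.314 changes by tens of percent as the
  fourth decimal of the coefficient moves.
- **Posttreatment-GFR model**: OLS with main effects pretreatment GFR, BSA,
  volume, surface area and candidate interactions BSA×volume and
  BSA×surface-area; interactions significant at p < 0.05 in the full model
  are retained and the model refit. No multiple-testing correction is applied
  anywhere in the pipeline, deliberately.

## Cohort simulator

`simulate_cohort` draws covariates from marginals defaulting to the
population this pipeline targets: volume mean 558.4 cm³ (SD 532), surface
area 1261.7 cm² (SD 1158.5) — both moment-matched lognormals (positivity)
coupled by a Gaussian copula with correlation 0.7, since large compartments
have large surfaces; BSA N(1.92, 0.25²); pretreatment GFR N(96, 35.5²)
clipped at 5; age N(60, 13²) clipped to 21–83; 50 % female, 11 % biphasic,
26 % residual disease > 0.5 cm. Survival is exponential with baseline median
48 months and log-hazard Σβx on raw covariate scales; censoring is
independent exponential with rate λ_c = λ̄ · f/(1 − f) for target censoring
fraction f (calibrated at the cohort's mean hazard, so the realized fraction
is approximate). Posttreatment GFR comes from the linear model (default
coefficients 0.802·preGFR + 69.969·BSA + 0.154·V − 0.003·SA − 0.07·V·BSA,
zero intercept) plus N(0, 10²) noise. Everything is deterministic given the
seed.

## Validation experiment sizes and numerical choices

The end-to-end checks use: a 2×3×4 cm box at 0.1 cm isotropic spacing (exact
quantification); 100 random labeled masks up to 32³ against the brute-force
face enumerator (bit-exact, by combining identical integer face counts with
identical arithmetic); a radius-2 cm sphere at 0.2/0.1/0.05 cm; 128³
three-compartment phantoms (noiseless Dice = 1.0, σ = 20 noise Dice ≥ 0.90);
100 simulated cohorts of n = 1000 with a true HR of 2 and 30 % censoring for
Cox recovery, with the null-covariate calibration measured over 800
replicates so that the Monte Carlo standard error (≈0.8 %) is small against
the 3–7 % acceptance band; and 100 cohorts of n = 500 for the GFR model
(coefficient 2-SE coverage, interaction retention ≥ 90 %, null-interaction
retention ≈ 5 %).

Ties in component ordering are broken by minimum coordinate; segmentation is
deterministic throughout — the only randomness in the package lives in the
generators, and every stochastic test carries an explicit seed.

## Known limitations

- Thresholds are global; intensity inhomogeneity (e.g. contrast dilution
  gradients) can fragment a compartment. The edit interface is the escape
  hatch, as in the original workflow.
- The voxel-face surface area overestimates the Euclidean area of smooth
  surfaces by the ℓ1 factor (≈1.5 for isotropic spheres, spacing-dependent
  for anisotropic voxels); comparisons are meaningful within a fixed protocol,
  not across voxel geometries.
- The censoring calibration in the simulator is exact only under a null
  hazard; with strong covariate effects the realized censoring fraction
  drifts a few points.
- NIfTI orientation matrices are not resampled; volumes are treated in their
  stored (x, y, z) axis order.
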