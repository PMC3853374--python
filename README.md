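# periquant — quantitative CT peritoneography

Catheter-administered intraperitoneal (IP) chemotherapy treats peritoneal
surface-spreading malignancies (malignant peritoneal mesothelioma, advanced
ovarian carcinoma) by bathing the peritoneum in drug — but only the
compartment the infusate actually reaches. CT peritoneography, a CT scan
after injecting diluted iohexol through the IP catheter, images that
compartment directly. `periquant` turns such scans into numbers: it segments
the contrast-filled compartments semi-automatically, measures their **volume**
and **surface area** by voxel-literal formulas, and runs the outcome
statistics — survival models and renal-function regression — that connect
those measurements to how patients fare.

It is aimed at imaging and clinical-research groups who need a reproducible,
scriptable implementation of compartment quantification and its companion
analysis, with synthetic phantoms and cohort simulators providing exact
ground truth for validation.

## The core quantities

For a labeled compartment mask on a grid with voxel spacing (dx, dy, dz) in
cm:

- **Volume** `V = N · dx · dy · dz` (cm³), with N the compartment's voxel
  count.
- **Surface area** `SA = Σ exposed voxel faces` (cm²): every face of a
  compartment voxel whose neighbor is non-compartment contributes the product
  of the two spacings spanning that face (dy·dz, dx·dz or dx·dy).
- **SA:V** (cm⁻¹): spherical, loculated pockets minimize it; free-flowing
  films of contrast maximize it, and a high SA:V means more drug in contact
  with more peritoneal surface.

Segmentation: an intensity band [100, 600] (diluted contrast is brighter than
soft tissue, darker than bone) plus connected components on a user-chosen ROI
slice, propagated iteratively to neighboring slices by a fractional-overlap
rule. The statistics stage provides Kaplan–Meier estimates, Welch t-tests,
a univariate Cox screen (p < 0.1) feeding a multivariate Cox model in which
compartment volume and surface area always appear, per-standard-deviation
hazard ratios `exp(β·SD)`, and an ordinary-least-squares model of
posttreatment GFR that retains only significant (p < 0.05) BSA×metric
interactions. Clinical scalars (Mosteller BSA, Cockcroft–Gault clearance,
trapezoidal plasma AUC) are included. See `docs/methods.md` for the full
model description.

## Worked example

Segment a noisy three-compartment synthetic peritoneogram from a single ROI
slice and quantify it (`examples/segment_phantom.py`):

```
compartments found: 3 (truth: 3)
  truth compartment 1: Dice = 0.9999
  truth compartment 2: Dice = 0.9999
  truth compartment 3: Dice = 0.9999
total volume      :    142.2 cm^3
total surface area:    271.4 cm^2
```

Despite Gaussian noise of 20 intensity units, each recovered compartment
overlaps its ground truth almost perfectly (Dice ≈ 1), and the bone-like
distractor in the phantom is excluded by the intensity band. On the
statistics side (`examples/cohort_analysis.py`, simulated 400-patient cohort
with a known hazard structure):

```
KM median survival: 55.7 months (95% CI 42.8-81.2), 226/400 events
multivariate model (volume and surface area always included):
    volume               HR = 1.0002 (0.9999-1.0005), p = 0.2497
    surface_area         HR = 0.9993 (0.9991-0.9995), p = 0.0000
    biphasic             HR = 3.7951 (2.5690-5.6065), p = 0.0000
    residual_gt_0_5cm    HR = 4.5617 (3.3528-6.2064), p = 0.0000
per-SD hazard ratio, surface area (SD = 1202 cm^2): 0.432 (0.334-0.557)
```

The per-unit hazard ratio of a covariate spanning thousands of cm² rounds to
1.000; expressed per standard deviation the protective surface-area effect
(true β = −0.0006 per cm² in the generator) is plainly visible.

Other examples: `phantom_quantification.py` (a 2×3×4 cm box measured at
exactly 24 cm³ / 52 cm²), `loculation_contrast.py` (equal-volume sphere vs
thin sheet, SA:V ratio > 3), `clinical_formulas.py`.

A thin CLI wraps the same library calls:

```sh
periquant phantom  --spec spec.json --out vol.nii.gz --mask gt.nii.gz
periquant segment  --in vol.nii.gz --roi 20,0,0,63,63 --out mask.nii.gz
periquant quantify --mask mask.nii.gz --out metrics.csv
periquant clinical bsa --height 180 --weight 80
periquant analyze  --table cohort.csv --out report/
```

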