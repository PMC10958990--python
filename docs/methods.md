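# Methods

`pseudodxa` simulates the measurement chain that links femoral-neck (FN)
structure to DXA-style densitometry and whole-bone strength, and provides the
statistical machinery used to compare strength–density associations between
groups. This note records the models, the calibrated defaults and where they
come from, the numerical choices, and the limits of what the synthetic data
can show.

## The phantom model

Each donor's FN volume of interest (VOI) is an idealized straight tube:

* **Cross-section**: an elliptical annulus with superior–inferior (SI) outer
  semi-axis `a = FNW/2`, anterior–posterior (AP) semi-axis `b = a × r` where
  `r` is the AP/SI width ratio (circularity), and a uniform cortical wall of
  thickness `t`. The inner (endosteal) boundary is the ellipse with both
  semi-axes reduced by `t`. True offset curves of an ellipse are not
  ellipses; the reduced-axes ellipse is the standard idealization and is what
  the closed-form section properties below describe.
* **Interior**: an independent Bernoulli voxel field at the target trabecular
  volume fraction (BV/TV), smoothed by one 3×3×3 morphological closing to
  create connected structure, then randomly trimmed or topped up so the
  realized fill equals the target count (well inside the one-percentage-point
  contract).
* **Axis convention**: axis 0 = AP (out of the DXA plane), axis 1 = SI,
  axis 2 = neck axis. The default VOI length is 15 mm (the clinical
  Hologic-style FN ROI width), rendered at 0.3 mm isotropic voxels. A voxel
  must be no larger than half the cortical thickness, or the builder raises a
  resolution error.

Every measured quantity in the analysis is defined on this 15-mm VOI, so a
prismatic tube exercises the identical measurement code that a curved neck
would, at a fraction of the cost. An optional linear taper exists for
experiments where slab placement must matter (e.g. the extraction
reliability study).

Closed-form ground truth for the prismatic geometry (`analytic_fn_params`):
projected area `= FNW × L`; Ct.Ar `= π[ab − (a−t)(b−t)]`;
`I_AP = (π/4)[b a³ − b'a'³]` (SI distances), `I_SI = (π/4)[a b³ − a'b'³]`
(AP distances), plus a uniform-density `BV/TV` contribution from the
interior; Tt.Ar `= πab`; Tt.Vol `= Tt.Ar × L`. The voxel pipeline reproduces
these to well under 1% at 50 µm and to ~0.5% at 0.3 mm (the moments over the
stochastic interior carry ~1% sampling error), and the discretization error
contracts as the voxel shrinks — this is the package's primary
oracle-equivalence check.

## PseudoDXA projection and units

A pseudoDXA image is the AP-ray projection of a compartment's voxels onto the
(neck, SI) plane. Pixel values are projected voxel counts, so the image sum
equals the compartment voxel count exactly, cortical + trabecular images add
pixelwise to the total, and nothing is interpolated. From the total image:

* **area** — the bone silhouette (pixels with any projected bone) times the
  pixel area, in cm². The silhouette definition (not the rectangular ROI) is
  the one consistent with DXA practice and with 4.7–5.4 cm² areas for a
  1.5-cm ROI; whether a minimum-thickness cutoff should apply instead is an
  open choice, flagged here and settled as "any bone".
* **BMC** — total projected bone voxels, expressed in units of 10⁶
  *reference voxels* of 27 µm edge (the nano-CT acquisition voxel), i.e. a
  count at voxel size `h` is scaled by `(h/0.027)³`. This keeps BMC
  comparable across rendering resolutions; an optional mass conversion is
  deliberately not applied.
* **aBMD** — `BMC / area`, exact by construction (an asserted invariant).
* **FNW** — per neck-axis column, the SI extent of nonzero pixels; the mean
  and minimum over columns are the average and minimum FN widths.

## Image-processing stages

* **HU calibration**: two-point linear map anchored on the scan phantom's
  air (−1000 HU) and water (0 HU) readings; the hydroxyapatite reading is a
  drift-monitoring QC value only and does not enter the map.
* **Rotation** (anteversion, default 15° about the SI axis): scipy affine
  resampling, nearest-neighbor for labels and trilinear for intensities. The
  grid is enlarged to the rotated bounding box by *symmetric,
  parity-preserving* padding and rotated in place, so the rotation center
  coincides exactly with the grid center; without this, the half-voxel center
  shift of a parity change silently deletes one face of the body (~2% of a
  50-slice tube). Multiples of 90° take a lattice-exact path.
* **VOI extraction**: a slab of `round_half_up(width / spacing)` slices
  perpendicular to the neck axis, centered at a configurable coordinate
  (volume center by default, which is the natural placement for synthetic
  prismatic volumes). Repeated extraction with identical settings is
  bit-identical; with sub-voxel placement jitter on tapered phantoms the
  projected area and BMC have ICC(2,1) > 0.999.
* **Bone segmentation**: a recorded global threshold (fixed 800 HU by
  default, or Otsu), with ties going to background. At the two-level phantom
  contrast (bone 1500 HU, background −200 HU) and 100 HU Gaussian noise the
  mask is essentially exact (Dice ≥ 0.999).
* **Cortical/trabecular partition**: deterministic morphology in three
  steps — (1) the periosteal region is the hole-filled closing of the bone
  mask (ball radius 1.0 mm by default); (2) the endosteal region is the
  largest connected component of the closed interior pore space; (3) a
  solid-core test reassigns to trabecular any bone voxel in a one-voxel band
  around the endosteal region that does not survive a one-voxel opening,
  recovering trabecular struts that abut the endosteal wall. Step 3 is this
  package's addition: without it those struts are systematically labeled
  cortical and the compartment readouts shift by ~6%. With it, cortical Dice
  against generator truth is ≥ 0.99 on cohort-scale phantoms and all
  downstream parameters agree with the label-bypass route to ~1% (the 1.0-mm
  default radius was selected on labeled phantoms; larger radii gain nothing
  and cost ~10× the time). The partition is exhaustive and exclusive over
  the mask. No manual correction pass exists; the run manifest records this.
  On synthetic cohorts the pipeline defaults to measuring the generator
  labels directly (`use_segmentation=False`), which the manifest also
  records.

## Strength model and cohort calibration

Strength (N) is linear in the donor's *ground-truth* structural traits plus
covariates and Gaussian noise:

```
strength = 1423.4 + 21.8·BMC_ct + 29.3·BMC_tb − 281·area + 136.9·sex − 6.0·age + 0·PYD + N(0, 810.9)
```

with BMC in 10⁶ reference voxels, area in cm², age in years, sex coded
female = 0 / male = 1. The trait and age coefficients are the reference
multivariable model's values. PYD (post-yield deflection) is sampled from
per-sex truncated normals (2.0 ± 1.2 mm female, 2.6 ± 1.5 mm male, floored
at 0) rather than derived from a load–displacement curve, and its default
coefficient is zero; it exists so the four-model regression ladder is
well-defined. Strength is floored at 1 N (with a warning) in the rare case
noise drives it negative — the one nonlinearity, responsible for a small
(≲3%) attenuation visible in coefficient-recovery experiments.

Remaining constants are calibrated, each derived once, analytically or from
large-n noiseless analytic cohorts, and then frozen:

* **Geometry distributions** (per sex, truncated normals): SI width from
  projected area / VOI length (female 31.33 ± 1.73 mm, male 36.20 ± 2.47 mm);
  cortical thickness from cortical BMC via the annulus area (1.211 / 1.303 mm,
  SD chosen so the compartment BMC SDs match after removing the
  width-variance contribution); BV/TV from trabecular BMC over the endosteal
  volume (0.137 / 0.152); circularity 0.84 ± 0.06 female vs 0.92 ± 0.06 male
  (no reference mean is printed; the values encode the observed
  "male necks are more circular" contrast); ages 67.8 ± 19.0 (24–97) and
  59.8 ± 19.1 (18–89) years. Mild age trends (−0.004 mm/yr on thickness,
  −0.0008/yr on BV/TV) are applied around each sex's mean age, so group means
  stay calibrated while age adjustment has something real to remove.
  Truncated-normal samplers re-solve the parent location so the *truncated*
  mean equals the requested mean; with asymmetric bounds (the age ranges)
  naive truncation would bias every calibrated mean.
* **Intercept 1423.4 N**: sets the expected female strength to 3108.2 N
  given the female trait means.
* **Noise SD 810.9 N**: makes the realized female strength SD 1037.9 N after
  accounting for the deterministic trait variance (647.8 N at the calibrated
  geometry SDs).
* **Sex offset +136.9 N**: chosen so the *expected common-slope ANCOVA group
  coefficient* of strength on BMC is zero after age adjustment
  (`calibrate_sex_offset` reproduces the derivation; two independent 200k/sex
  runs agree to 0.5 N). This is the study condition the mechanism analysis
  assumes — male and female femurs of equal BMC are equally strong, and the
  sex-specific association appears only when BMC is divided by a size
  measure. Note the elevation *test* examines the common-slope group
  coefficient, not the separate-fit midpoint-elevation difference; with
  sex-specific slopes and x-ranges the two differ (~200 N here), and
  calibrating the wrong one leaves a residual gap the test detects at large
  n. A consequence of zeroing the BMC gap with the reference trait
  coefficients is that the synthetic male strength mean sits near 4.7 kN
  rather than 5.2 kN; all direction-of-difference contrasts (male > female
  for strength, area, BMC, aBMD; female > male for % cortical) are preserved.

Strength is synthesized from analytic (true) traits and the regressions run
on voxel-measured traits — the realistic data-generating direction, with
measurement error entering only where it does in reality.

## Statistical procedures

* Descriptives: mean ± SD and range per sex with pooled-variance two-sided
  t-tests (Welch available by flag); D'Agostino–Pearson omnibus normality
  (requires n ≥ 20).
* **Age adjustment**: within each sex, each variable is regressed on age and
  every observation moved along that line to 65 years
  (`adjusted = observed + slope × (65 − age)`); slopes are logged in the run
  manifest. Adjustment is per sex, not pooled — pooled adjustment would
  transfer the 8-year mean age gap between sexes into every adjusted
  variable. All regressions and ANCOVAs run on adjusted data (an unadjusted
  sensitivity pass is available).
* **ANCOVA comparison** (`ancova_compare`): slope equality via the group×x
  interaction; elevation equality via the group term of the common-slope
  model; per-group *elevations* are the OLS intercepts after shifting x by
  the midpoint of the pooled x range, with standard OLS intercept CIs, and
  the difference CI combines the per-group intercept SEs. Under a null
  simulation the elevation test's type-I error is nominal (within
  [0.03, 0.07] at α = 0.05 over 1000 replicates, n = 50/group), and an
  injected 1045 N offset is recovered with ~95% CI coverage.
* **Percent differences** use the percent-of-mean convention
  `100·(M − F)/((M + F)/2)` throughout. This convention is the only one
  under which the published elevation pairs reproduce their published
  percent differences (12.4, 25.4, 25.6, 33.1, 42.9) and under which the
  idealized-shape gain triple (12, 18, 54) is mutually consistent.
* **Multivariable models**: OLS with unstandardized B and 95% CI,
  standardized β = B·SD(x)/SD(y), per-term p, VIF; while any VIF exceeds 10
  the worst term is dropped and the fit repeated, with removals logged. No
  multiple-testing correction anywhere (α = 0.05 per test, matching the
  analysis being reproduced).
* **ICC**: two-way random effects, absolute agreement, single measure
  (ICC(2,1), via pingouin), the appropriate form for repeated-extraction
  reliability.

## The idealized-shape fit (`fig6_fit_predict`)

For a circular and an elliptical annulus with equal SI width and equal wall
thickness, the percent-of-mean gains of the circle in Ct.Ar (∝ BMC), in
bending resistance about the horizontal axis (Ixx, SI distances) and about
the vertical axis (Iyy, AP distances) are functions of two dimensionless
shape parameters (AP/SI ratio, thickness/SI-semi-axis). Given any two gains
the solver (bounded least squares from multiple starts, residual tolerance
10⁻⁶) recovers the shape and predicts the third. Fitting (BMC 12%, Ixx 18%)
predicts Iyy ≈ 53.9%; (BMC 12%, Iyy 54%) predicts Ixx ≈ 18.0%; (Ixx 18%,
Iyy 54%) predicts BMC ≈ 11.7% — the published triple is consistent to within
one percentage point. Gains of exactly (0, 0) mean identical shapes; the
thickness is then indeterminate and the predicted third gain is returned as
0 directly.

## What the synthetic cohorts do and do not show

The generator is a calibration device, not a claim about donors: no
generative model exists for the real anatomy, and every distributional choice
above was made to match published summary statistics. Passing tests
demonstrate that the *measurement and statistical machinery* behaves as
specified on geometry whose ground truth is known exactly — conservation
identities hold, voxel measures converge to closed forms, the ANCOVA
machinery is calibrated, the generator's injected structure is recovered —
and that the size-adjustment mechanism (dividing BMC by FNW, area^1.5, or
Tt.Ar creating a sex-specific strength association where raw BMC shows none)
emerges on cohorts with the calibrated structure. They do not validate the
phantom against real bone: there is no neck curvature or trochanter, no
cortical thickness variation around the circumference, no trabecular
anisotropy, no X-ray physics (scatter, beam hardening, detector response),
and in a prismatic tube BMC/FNW is *exactly* proportional to aBMD (area =
FNW × L), so those two regressions coincide rather than merely correlate.
Real-data claims require real images; the volume I/O (NIfTI), HU
calibration, rotation and VOI extraction accept them, but anatomical
landmark detection is out of scope.

## Problem sizes and numerical defaults

Default rendering is 0.3 mm voxels (≈0.5 M voxels per donor; the package's
chosen operating point for cohort studies — oracle agreement there is ~0.5%).
Oracle-equivalence checks run at 50/25 µm on short tubes. The calibration
experiments use 1000 null replicates (type-I), 500 replicates each for
offset coverage and coefficient recovery (n = 95), and the mechanism
contrast uses 5 seeds × 200 donors/sex. Master seeds spawn per-donor seeds
(stored in the donor table) so any volume regenerates exactly; all outputs
are pure functions of (spec, seed). Degenerate inputs fail loudly:
empty cohorts, empty projections (aBMD undefined), neck-axis columns without
bone, zero x-variance groups, sub-voxel closing radii, and voxels coarser
than half the cortical thickness all raise typed errors.
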