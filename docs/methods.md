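# Methods

## The measurement model

CT-derived waist circumference is defined as the length of the outer margin
of the abdominal skin on one axial slice: the slice midway along z between
the lowest rib margin and the highest iliac crest margin, which mirrors the
landmark rule used for tape measurements. The pipeline has five stages:

1. **Canonical orientation.** Volumes are resampled to axis order (z, y, x)
   with z superior, y anterior, x subject-left; all indices downstream are
   interpreted in this frame. Physical position is `index × spacing`
   (slice-center convention). NIfTI input goes through nibabel's closest
   canonical transform; DICOM series are sorted by physical z and converted
   to HU via rescale slope/intercept.
2. **Segmentation.** Body mask: HU > −400, largest 3D 26-connected
   component (suppresses the patient table and clothing), then per-axial-
   slice 2D hole filling so lung and bowel gas become interior. The fill is
   deliberately 2D: a 3D fill would wrongly close the open inferior end of
   the torso at the scan boundary. Bone mask: HU ≥ +200 with components
   below 500 mm³ removed. The thresholds are the standard classical choices
   for noncontrast CT at ~3 mm slices; both are configurable. A learned
   multi-class segmentation could replace this stage without touching the
   rest of the pipeline.
3. **Landmarking.** The bone mask is max-projected along y into a coronal
   (z, x) image. The body mask supplies a midline x_c and mean half-width w;
   a central exclusion band of width 0.30 × (2w) centred on x_c removes the
   vertebral column and sacrum from consideration. A z level has "lateral
   bone" if any projected pixel falls outside the band. The waist gap is the
   longest run of consecutive lateral-bone-free levels that has lateral bone
   both above (ribs) and below (iliac wings); runs shorter than
   `min_gap_slices` (default 2) do not qualify, and ties in length go to the
   more superior run because the anatomical gap abuts the costal margin.
   The measured slice is `⌊(z_rib + z_iliac)/2⌋` — the floor makes the
   odd-gap tie-break deterministic and errs by at most one slice (~3 mm),
   below measurement resolution. Slices with body area under 10% of the
   median are excluded as scan ends. The lateral-band rule is this package's
   concretization of projection-based landmarking; it is deliberately simple
   and is stress-tested by phantoms with posterior rib tails crossing the
   midline (`hard_mode`).
4. **Evaluability.** If any body-mask pixel of the selected slice lies on
   the in-plane image border, the contour would be clipped open and the scan
   is reported `non_evaluable` rather than measured. Landmarking failures
   (no lateral bone, no qualifying gap) are `technical_failure`. In batch
   bookkeeping the three statuses partition the inputs, so both an overall
   technical-efficacy rate and a sufficient-FOV rate (excluding
   non-evaluable scans from the denominator) can be formed.
5. **Contour and perimeter.** The skin line is the marching-squares
   iso-contour of the binary mask at level 0.5, choosing the closed contour
   with the largest enclosed area. A sub-pixel note: on binary input,
   marching squares yields a 45° staircase polygon whose length
   overestimates a smooth boundary by ~5–6% regardless of resolution. The
   polygon is therefore regularized with a 5-point circular moving average
   of its vertices, which restores sub-pixel placement (length error < 0.5%
   on discs and ellipses at clinical resolutions, verified against the
   Ramanujan perimeter and numeric arc length). Contours with fewer than 16
   vertices are left untouched so degenerate lattice cases (e.g. a single
   pixel → the diamond through its edge midpoints, perimeter 2√2 px) remain
   exact. Smoothing is linear, so it commutes with the per-axis mm scaling
   and preserves exact linear scaling of the perimeter with spacing.
   The perimeter — the sum of segment lengths — is reported in cm to
   0.1 cm. An iso-contour rather than the convex hull is essential: the
   measure is the skin perimeter *including* surface irregularities, which
   a hull would erase.

## Phantoms

`generate_phantom` paints a torso with known geometry on an arbitrary grid
(defaults: 64 slices of 256 × 256 voxels at 3 × 1.5 × 1.5 mm): an
elliptical soft-tissue cross-section (+40 HU in −1000 HU air; per-slice
semi-axes configurable), thin lateral rib arcs over a superior z range,
iliac wings plus a central sacrum block over an inferior range, an optional
central spine column, optional Gaussian HU noise, an optional table bar
(tests the largest-component rule), and an optional FOV crop (tests
evaluability). Ground truth is exact by construction: the landmark slices
are the painted z limits and the true WC is the Ramanujan ellipse perimeter
π(3(a+b) − √((3a+b)(a+3b)))/10 of the mid-waist ellipse (cross-checked
against numeric arc-length integration in the tests).

What the phantom does *not* emulate: organ texture, realistic trabecular
bone, partial-volume blur, beam hardening, arms, or anatomical asymmetry.
Passing the phantom battery therefore demonstrates the geometric
correctness of the pipeline (landmark logic, contour accuracy, failure
triage), not clinical robustness on real scanners.

## Cohort simulator

`generate_cohort` draws per subject: sex (P(female) = 326/757); manual WC ~
N(80.4, 8.5²) cm for women, N(88.9, 7.6²) cm for men; CT WC = manual WC +
sex-specific offset + noise, with defaults 5.1 ± 4.3 cm (women) and
6.8 ± 3.7 cm (men) — the supine/inspiration/skin-perimeter offset structure
observed when CT and tape measurements are compared. BMI is an affine
function of manual WC with sex-specific slope (0.35 / 0.34 kg/m² per cm,
chosen from the marginal SD ratio times a typical WC–BMI correlation) and
intercept fixed by the convention that the 85 cm (women) / 90 cm (men)
cutoffs correspond to BMI 25 kg/m², plus N(0, 1.2²) noise. The affine link
is a modeling choice, not an estimated joint distribution: it gives ROC
analyses a realistic, tunable signal. It slightly overshoots the women's
marginal mean BMI (≈23.4 vs ≈22.4 observed in screening populations with
these WC marginals), a consequence of forcing the cutoff correspondence
exactly. An optional second visit applies Δmanual ~ N(−1.4, 4.0²) cm and
ΔCT = Δmanual + N(−0.3, 4.5²); this matches the mean and SD of interval-
change differences but is not separately calibrated to an interval-change
correlation (the three summary numbers are not jointly attainable under any
additive model).

Under these defaults the pooled Pearson correlation between the two WC
measurements is analytically ≈0.92 (between-sex mean separation plus
within-sex noise), which is what the parameter-recovery tests assert as a
pre-registered band (0.89–0.95 at n = 757).

## Statistics

- **Pearson r** via scipy, CI by Fisher z-transform, p from the t
  distribution with n−2 df.
- **Bland–Altman**: differences x−y, SD with n−1 denominator, LoA =
  mean ± 1.96·SD. At n = 10 000 with Gaussian noise the LoA contain
  93.5–96.5% of differences (tested).
- **ICC(C,1)**: two-way model, single measures, consistency definition
  (MS_rows − MS_err)/(MS_rows + MS_err) with k = 2; CI from the
  McGraw–Wong F bounds. Matches an independent from-scratch ANOVA oracle to
  1e−10 and pingouin's ICC(C,1) row.
- **ROC**: AUC by the tie-corrected Mann–Whitney formulation (verified
  against exhaustive pair enumeration for n ≤ 12 and against
  scikit-learn); CI and the paired two-AUC comparison use DeLong's
  structural components — DeLong is the standard paired method behind the
  "z-test" label in common clinical statistics software. Identical score
  vectors short-circuit to z = 0, p = 1. The Youden-optimal cutoff searches
  midpoints between consecutive sorted unique scores with "positive" meaning
  value ≥ cutoff; ties on J prefer higher specificity, then the lower
  cutoff (deterministic and screening-oriented; no convention is universal).
  Type-I error control of the paired test is checked by a null simulation
  (p uniform on [0, 1] by KS test).
- **McNemar**: exact two-sided binomial for b + c ≤ 25, chi-square with
  continuity correction above (the standard switch point); b = c = 0 gives
  p = 1.
- **Cross-tabulations** are 2 × 2 × 4 count arrays (CT class × manual class
  × BMI category) with the cutoffs carried alongside; sensitivity/
  specificity treat overweight + obesity columns as disease-positive, and
  all percentages are reported to 0.1 with raw fractions. The bundled
  example counts contain two internal roundings worth knowing: direct
  summation gives women's CT specificity 242/262 = 92.4% and men's
  concordance 372/431 = 86.3%; the package always reports the value implied
  by the counts.

## Numerical and design choices

- Spacings read from NIfTI are rounded to 1e−6 mm because the format stores
  them as float32; this restores the exact decimal spacings scanners use.
- Voxels are float32 throughout; round-trips are exact.
- `perimeter_cm` rounds to 0.1 cm by default (reporting precision);
  invariance tests that need exact linearity use the unrounded value.
- Degenerate inputs fail loudly with typed errors (`DataError`,
  `TechnicalFailure`, `NonEvaluable`) and the pipeline folds them into the
  report status instead of propagating.
- Problem sizes in the test battery and the acceptance script (9-phantom
  recovery grid, n = 757 cohorts, 200-replicate oracle sweeps) were chosen
  as the smallest sizes at which the tested statistical bounds are sharp.

## Known limitations

- Threshold segmentation has no notion of arms-down scans, metal artefacts,
  or contrast phases; the landmark heuristic assumes a supine, roughly
  centred subject in anatomical orientation.
- The lateral-band gap rule can fail on severe scoliosis or rib anomalies —
  by design it then reports `technical_failure` rather than guessing.
- Cutoff transfer: CT WC is systematically offset from tape WC, so tape
  cutoffs must not be applied to CT values without recalibration; the
  cross-tabulation tools exist precisely to study that offset.
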