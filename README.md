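# ctwaist

Automated waist-circumference (WC) measurement on abdominal CT, with the
synthetic phantoms and method-comparison statistics needed to validate it.

Waist circumference is a standard anthropometric marker of central obesity,
normally taken with a tape measure at the mid-point between the lower costal
margin and the iliac crest. The same quantity can be extracted from an
abdominal CT scan with no extra examination: segment the body and the bone,
find the bone-free gap between the lowest rib margin and the highest iliac
crest on the antero-posterior projection of the bone mask, take the axial
slice midway through that gap, and measure the length of the outer skin
contour there. `ctwaist` implements that pipeline for researchers working on
CT body composition, plus everything around it:

- **Pipeline** — NIfTI/DICOM reading with canonical anatomical orientation;
  Hounsfield-threshold body (−400 HU) and bone (+200 HU) masks; coronal
  max-projection landmarking; sub-pixel marching-squares skin contour;
  WC in cm to 0.1 cm. Scans whose body exits the field of view are flagged
  `non_evaluable`; failed landmarking is a `technical_failure`.
- **Phantoms** — seeded synthetic CT torsos (elliptical body, lateral rib
  arcs, iliac wings, spine, optional table bar / FOV crop / HU noise) with
  exact analytic ground truth, and seeded paired WC cohorts (sex, manual WC,
  CT WC, BMI) with configurable offset/noise structure.
- **Statistics** — Pearson r with Fisher-z CI, Bland–Altman limits of
  agreement, ICC(C,1) with McGraw–Wong CI, ROC AUC with DeLong CI and
  paired DeLong z-test, Youden-optimal cutoffs, McNemar tests, and
  2 × 2 × BMI-category cross-tabulations with per-method sensitivity,
  specificity and concordance.

The core measurement is the perimeter of the closed iso-contour of the
filled body mask at the mid-waist slice z\*:

> z\* = ⌊(z_rib + z_iliac) / 2⌋,  WC = Σᵢ ‖vᵢ₊₁ − vᵢ‖ / 10 cm,

with contour vertices v in mm after per-axis spacing scaling.

## Worked example

```sh
python examples/measure_phantom.py
```

```
status           : success
measured WC      : 79.7 cm
true WC          : 79.3 cm (Ramanujan perimeter of the mid-waist ellipse)
mid-waist slice  : 32 (truth 32)
lowest rib slice : 40
iliac crest slice: 24
recovery error   : 0.47%  (sub-pixel contouring keeps this under 1%)
```

A 150 × 100 mm elliptical torso has true perimeter 79.33 cm (Ramanujan);
the pipeline finds the painted rib (slice 40) and iliac (slice 24)
landmarks exactly, selects slice 32, and recovers the circumference to
within half a percent despite 10 HU of added noise.
`examples/cohort_statistics.py` and `examples/crosstab_worked_example.py`
walk through the validation statistics the same way.

## Command line

```sh
ctwaist phantom --out vol.nii.gz --truth truth.json --seed 3
ctwaist measure vol.nii.gz --json report.json
ctwaist batch volumes/ --csv results.csv
ctwaist simulate-cohort -n 757 --seed 17 --csv cohort.csv
ctwaist validate --cohort cohort.csv --report report.json
```

Exit codes: 0 success, 2 usage error, 3 data error. Identical seed and
configuration give byte-identical outputs.

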