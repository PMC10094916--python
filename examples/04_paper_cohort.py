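"""Build and analyze the packaged 12-patient synthetic cohort end to end.

Generates paired before/after hyperspectral cubes for all 12 virtual
patients (ENVI files + white reference), runs the full pipeline
(calibration -> gray conversion -> GLCM metrics -> 654 nm band metrics ->
paired cohort statistics) and prints the cohort summary.
"""

import tempfile

from hyperskin.pipeline import analyze_manifest
from hyperskin.simulate import build_cohort, paper_preset

preset = paper_preset()
with tempfile.TemporaryDirectory() as tmp:
    manifest = build_cohort(preset, tmp)
    result = analyze_manifest(manifest)

summary = result.summary
print(f"{'metric':12s} {'before (mean±SD)':>20s} {'after (mean±SD)':>20s} "
      f"{'inc/dec/tie':>12s} {'p (Wilcoxon)':>12s}")
for key, ms in summary.metrics.items():
    print(f"{key:12s} {ms.mean_before:12.2f}±{ms.sd_before:6.2f} "
          f"{ms.mean_after:12.2f}±{ms.sd_after:6.2f} "
          f"{ms.n_increase:4d}/{ms.n_decrease}/{ms.n_tie} {ms.wilcoxon_p:12.4f}")

b = summary.metrics["brightness"]
r = summary.metrics["refl_mean"]
print()
print(f"median paired brightness shift: {b.median_diff:+.2f} gray levels")
print(f"median 654 nm reflectance: {r.median_before:.1f} -> {r.median_after:.1f} c.u.")
print()
print("Brightness rises and contrast falls after treatment: the skin gets")
print("lighter and more even. The 654 nm reflectance increase tracks the")
print("drop in melanin absorption; p-values are paired two-sided Wilcoxon.")
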