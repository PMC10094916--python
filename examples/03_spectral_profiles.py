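"""Extract ROI spectral profiles and 654 nm absorption-band metrics.

Lifts a synthetic gray texture to a reflectance cube with a skin-like
spectrum (darker pixels = more melanin = uniformly lower reflectance),
then extracts the max/mean/min reflectance curves of the ROI and reads
them at the band nearest 654 nm.
"""

from hyperskin import ROI, band_metrics, roi_profiles
from hyperskin.envi import default_wavelength_grid
from hyperskin.simulate import gray_to_cube, pattern_synthesize, solve_step_distribution

wavelengths = default_wavelength_grid(204)  # 400-1000 nm, 2.941 nm steps

dist = solve_step_distribution(5.0, 0.6)
img = pattern_synthesize(140.0, dist, shape=(64, 64), seed=1)
cube = gray_to_cube(img, refl_mean_target_cu=854.0, wavelengths=wavelengths)

profile = roi_profiles(cube, ROI(0, 0, 64, 64))
bm = band_metrics(profile, lambda_nm=654.0)

print(f"analysis band: {bm.lambda_nm:.1f} nm (nearest grid band to 654 nm)")
print(f"ROI mean reflectance there: {bm.mean_cu:.2f} c.u.")
print(f"ROI max-min range there:    {bm.range_cu:.2f} c.u.")
print()
print("The max/min curves are the full spectra of the single brightest and")
print("darkest ROI pixels; the range at 654 nm measures how unevenly")
print("melanin is distributed across the patch. Lower melanin content")
print("raises reflectance at this band.")
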