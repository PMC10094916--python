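"""Write a raw ENVI cube, read it back and calibrate it to reflectance.

Builds a tiny 4x4x8 cube of raw sensor counts plus a white-reference cube,
round-trips both through the ENVI header+raw format, and converts counts to
reflectance in counts-units (c.u., 1023 = 100% reflectance against the
white panel).
"""

import tempfile
from pathlib import Path

import numpy as np

from hyperskin import HyperCube, calibrate, default_wavelength_grid, read_envi, write_envi

wavelengths = default_wavelength_grid(8)
rng = np.random.default_rng(0)

raw_counts = rng.integers(300, 900, size=(4, 4, 8)).astype(np.uint16)
raw = HyperCube(raw_counts, wavelengths)
white = HyperCube(np.full((4, 4, 8), 1200, dtype=np.uint16), wavelengths)

with tempfile.TemporaryDirectory() as tmp:
    hdr = Path(tmp) / "scene.hdr"
    write_envi(raw, hdr, interleave="bil")
    back = read_envi(hdr)
    assert np.array_equal(back.data, raw.data), "round trip must be bit-exact"
    refl = calibrate(back, white)

print(f"raw counts at pixel (0,0), band 0:      {raw.data[0, 0, 0]}")
print(f"white reference counts (all bands):     1200")
print(f"calibrated reflectance at (0,0), band 0: {refl.data[0, 0, 0]:.1f} c.u.")
print()
print("Reflectance = 1023 * raw/white, so e.g. raw 600 against white 1200")
print("gives 511.5 c.u. = 50% reflectance. Values are per band, per pixel.")
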