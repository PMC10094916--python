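"""Hyperspectral cube model and ENVI header+raw I/O.

The cube convention used throughout the package is 0-based, half-open,
``(row, col, band)`` axis order.  Calibrated reflectance is expressed in
counts-units ("c.u.") on a configurable scale where ``scale_cu`` (default
1023, a 10-bit-like scale) corresponds to 100 % reflectance against the
white calibration panel.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_SCALE_CU",
    "HyperCube",
    "ROI",
    "CohortManifest",
    "EnviFormatError",
    "EnviCorruptionError",
    "CalibrationError",
    "read_envi",
    "write_envi",
    "calibrate",
    "read_manifest",
    "write_manifest",
    "default_wavelength_grid",
]

#: counts-units value corresponding to 100 % reflectance (10-bit-like scale)
DEFAULT_SCALE_CU = 1023.0

# ENVI numeric codes <-> numpy dtypes (little-endian on write)
_ENVI_DTYPES = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Header is missing required fields or is internally inconsistent."""


class EnviCorruptionError(ValueError):
    """Binary data file does not match the dimensions the header declares."""


class CalibrationError(ValueError):
    """White/dark references are unusable (e.g. white <= dark in a band)."""


@dataclass
class HyperCube:
    """A hyperspectral image cube indexed ``(row, col, band)``.

    ``data`` holds raw sensor counts (``calibrated=False``) or reflectance in
    counts-units on the ``scale_cu`` scale (``calibrated=True``).
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    calibrated: bool = False
    scale_cu: float = DEFAULT_SCALE_CU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise EnviFormatError(f"cube must be 3-D (row, col, band), got {self.data.ndim}-D")
        if self.data.shape[2] == 0:
            raise EnviFormatError("cube must have at least one band")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise EnviFormatError(
                f"wavelength list length {len(self.wavelengths_nm)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise EnviFormatError("wavelengths must be strictly increasing")
        if np.any(self.data < 0):
            raise EnviFormatError("cube values must be non-negative")
        if self.scale_cu <= 0:
            raise EnviFormatError("scale_cu must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; 0-based, half-open bounds."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate ROI {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"negative ROI bounds {self}")

    def validate(self, cube: HyperCube) -> None:
        rows, cols, _ = cube.shape
        if self.row1 > rows or self.col1 > cols:
            raise ValueError(f"ROI {self} exceeds cube shape {rows}x{cols}")

    def extract(self, cube: HyperCube) -> np.ndarray:
        """ROI view of the cube data, shape (roi_rows, roi_cols, bands)."""
        self.validate(cube)
        return cube.data[self.row0 : self.row1, self.col0 : self.col1, :]

    def as_text(self) -> str:
        return f"{self.row0}:{self.col0}:{self.row1}:{self.col1}"

    @classmethod
    def from_text(cls, text: str) -> "ROI":
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise ValueError(f"ROI spec must be row0:col0:row1:col1, got {text!r}")
        return cls(*(int(p) for p in parts))


@dataclass
class CohortManifest:
    """Pairs each patient id with its before/after cube paths and ROI."""

    patients: list[tuple[str, str, str, ROI]] = field(default_factory=list)
    white_path: str | None = None

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique")


def default_wavelength_grid(n_bands: int = 204, start_nm: float = 400.0,
                            step_nm: float = 2.941) -> np.ndarray:
    """The camera's band grid: ``start + k*step`` for k = 0..n_bands-1.

    Defaults model a 400-1000 nm push-broom camera with ~2.9 nm resolution
    and 204 bands.
    """
    return start_nm + step_nm * np.arange(n_bands)


# --------------------------------------------------------------------------
# ENVI reading / writing

_REQUIRED_FIELDS = ("samples", "lines", "bands", "data type", "interleave")


def _parse_header(text: str) -> dict:
    """Parse an ENVI ASCII header into a key -> string/list dict."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header (missing ENVI magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, object] = {}
    # multi-line { } blocks first, then simple key = value lines
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*\{(.*?)\}", body, re.S | re.M):
        key = m.group(1).strip().lower()
        fields[key] = [v.strip() for v in m.group(2).split(",") if v.strip()]
    body_wo_blocks = re.sub(r"^\s*[\w ]+?\s*=\s*\{.*?\}", "", body, flags=re.S | re.M)
    for line in body_wo_blocks.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _data_path_for(header_path: str) -> str:
    stem, ext = os.path.splitext(header_path)
    if ext.lower() != ".hdr":
        stem = header_path
    for candidate in (stem, stem + ".raw", stem + ".img", stem + ".dat"):
        if os.path.isfile(candidate) and candidate != header_path:
            return candidate
    raise EnviFormatError(f"no data file found next to header {header_path!r}")


def read_envi(header_path: str | os.PathLike) -> HyperCube:
    """Read an ENVI header+raw pair into a (row, col, band) cube.

    Handles BIL, BIP and BSQ interleaves; the returned array layout is
    independent of the on-disk interleave.  The cube is returned with
    ``calibrated=False``; run :func:`calibrate` to convert counts to
    reflectance.
    """
    header_path = os.fspath(header_path)
    with open(header_path, "r") as fh:
        fields = _parse_header(fh.read())
    missing = [f for f in _REQUIRED_FIELDS if f not in fields]
    if missing:
        raise EnviFormatError(f"header missing required field(s): {', '.join(missing)}")
    if "wavelength" not in fields:
        raise EnviFormatError("header missing wavelength list")

    samples = int(fields["samples"])  # columns
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    dtype = _ENVI_DTYPES[code]
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = str(fields["interleave"]).lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"header declares {bands} bands but {len(wavelengths)} wavelengths"
        )

    data_path = _data_path_for(header_path)
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviCorruptionError(
            f"data file {data_path!r} holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":  # (band, row, col)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (row, band, col)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (row, col, band)
        cube = raw.reshape(lines, samples, bands)
    return HyperCube(np.ascontiguousarray(cube), wavelengths, calibrated=False)


def write_envi(cube: HyperCube, header_path: str | os.PathLike,
               interleave: str = "bsq") -> None:
    """Write a cube as an ENVI header (.hdr) + raw binary pair.

    Wavelengths are written with full float precision so a round trip is
    bit-exact.  The data file shares the header's stem with a .raw suffix.
    """
    header_path = os.fspath(header_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype = np.dtype(cube.data.dtype).newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        raise EnviFormatError(f"dtype {cube.data.dtype} has no ENVI type code")
    rows, cols, bands = cube.shape

    stem, ext = os.path.splitext(header_path)
    if ext.lower() != ".hdr":
        stem = header_path
        header_path = header_path + ".hdr"
    data_path = stem + ".raw"

    if interleave == "bsq":
        ondisk = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        ondisk = cube.data.transpose(0, 2, 1)
    else:
        ondisk = cube.data
    np.ascontiguousarray(ondisk, dtype=dtype).tofile(data_path)

    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    with open(header_path, "w") as fh:
        fh.write("ENVI\n")
        fh.write(f"samples = {cols}\n")
        fh.write(f"lines = {rows}\n")
        fh.write(f"bands = {bands}\n")
        fh.write("header offset = 0\n")
        fh.write(f"data type = {_DTYPE_CODES[dtype]}\n")
        fh.write(f"interleave = {interleave}\n")
        fh.write("byte order = 0\n")
        fh.write("wavelength units = Nanometers\n")
        fh.write("wavelength = {\n " + wl + "\n}\n")


# --------------------------------------------------------------------------
# Reflectance calibration


def _reference_spectrum(ref: HyperCube) -> np.ndarray:
    """Spatially average a reference cube to one spectrum per band."""
    return ref.data.reshape(-1, ref.n_bands).mean(axis=0)


def calibrate(raw: HyperCube, white: HyperCube,
              dark: HyperCube | None = None,
              scale_cu: float = DEFAULT_SCALE_CU) -> HyperCube:
    """Convert raw counts to reflectance against a white reference.

    Per band, ``reflectance = scale_cu * (raw - dark) / (white - dark)``
    where white and dark are spatially averaged reference spectra (dark
    defaults to zero).  Values that fall below zero after dark subtraction
    are clipped to zero rather than erroring, since they arise from sensor
    noise.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    if not np.allclose(raw.wavelengths_nm, white.wavelengths_nm):
        raise CalibrationError("raw and white cubes are on different band grids")
    white_spec = _reference_spectrum(white)
    if dark is not None:
        if not np.allclose(raw.wavelengths_nm, dark.wavelengths_nm):
            raise CalibrationError("raw and dark cubes are on different band grids")
        dark_spec = _reference_spectrum(dark)
    else:
        dark_spec = np.zeros_like(white_spec)
    denom = white_spec - dark_spec
    if np.any(denom <= 0):
        bad = np.flatnonzero(denom <= 0)
        raise CalibrationError(
            f"white reference does not exceed dark in band(s) {bad[:5].tolist()}"
        )
    refl = scale_cu * (raw.data.astype(float) - dark_spec) / denom
    np.clip(refl, 0.0, None, out=refl)
    return HyperCube(refl, raw.wavelengths_nm.copy(), calibrated=True, scale_cu=scale_cu)


# --------------------------------------------------------------------------
# Cohort manifest text format
#
# One patient per line: id, before path, after path, roi (row0:col0:row1:col1),
# whitespace separated.  An optional "# white: <path>" header line points at
# the shared white-reference cube.  Paths are stored relative to the manifest.


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    with open(path, "w") as fh:
        fh.write("# hyperskin cohort manifest\n")
        if manifest.white_path is not None:
            fh.write(f"# white: {os.path.relpath(manifest.white_path, base)}\n")
        fh.write("# patient_id\tbefore\tafter\troi\n")
        for pid, before, after, roi in manifest.patients:
            fh.write(
                f"{pid}\t{os.path.relpath(before, base)}\t"
                f"{os.path.relpath(after, base)}\t{roi.as_text()}\n"
            )


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    patients: list[tuple[str, str, str, ROI]] = []
    white: str | None = None
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*white:\s*(.+)", line)
                if m:
                    white = os.path.join(base, m.group(1).strip())
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"manifest line must have 4 fields: {line!r}")
            pid, before, after, roi_text = parts
            patients.append(
                (pid, os.path.join(base, before), os.path.join(base, after),
                 ROI.from_text(roi_text))
            )
    manifest = CohortManifest(patients=patients, white_path=white)
    for pid, before, after, _ in manifest.patients:
        for p in (before, after):
            if not os.path.isfile(p):
                raise FileNotFoundError(f"manifest references missing cube for {pid}: {p}")
    return manifest
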