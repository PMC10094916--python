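"""ROI spectral profiles and absorption-band metrics.

For a calibrated ROI three per-band curves are extracted: the spectrum of
the single brightest pixel (greatest band-mean reflectance), the per-band
mean over all ROI pixels, and the spectrum of the single darkest pixel.
Reading these curves at the band nearest a chosen analysis wavelength
(654 nm by default — the band the study used to track melanin) gives the
mean reflectance and the max−min range there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi import ROI, HyperCube

__all__ = [
    "DEFAULT_LAMBDA_NM",
    "SpectralProfile",
    "BandMetrics",
    "roi_profiles",
    "band_index",
    "band_metrics",
]

#: default analysis wavelength; decreased melanin raises reflectance here
DEFAULT_LAMBDA_NM = 654.0


@dataclass
class SpectralProfile:
    """Per-band max / mean / min reflectance curves of an ROI, in c.u."""

    wavelengths_nm: np.ndarray
    max_cu: np.ndarray
    mean_cu: np.ndarray
    min_cu: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        for name in ("max_cu", "mean_cu", "min_cu"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per band")


@dataclass(frozen=True)
class BandMetrics:
    """Reflectance statistics read at one analysis band."""

    lambda_nm: float
    mean_cu: float
    range_cu: float

    def __post_init__(self) -> None:
        if self.range_cu < 0:
            raise ValueError("reflectance range cannot be negative")


def roi_profiles(cube: HyperCube, roi: ROI, pointwise: bool = False) -> SpectralProfile:
    """Maximum, average and minimum reflectance curves of an ROI.

    The max (min) curve is the full spectrum of the single pixel with the
    greatest (least) band-mean reflectance, ties broken by row-major first
    occurrence.  With ``pointwise=True`` the max/min curves are instead the
    per-band pointwise extrema over all ROI pixels; when every pixel
    spectrum is a scalar multiple of one shared shape the two conventions
    coincide.
    """
    if not cube.calibrated:
        raise ValueError("cube must be calibrated before profiling")
    block = roi.extract(cube)
    flat = block.reshape(-1, cube.n_bands).astype(float)
    mean_cu = flat.mean(axis=0)
    if pointwise:
        max_cu = flat.max(axis=0)
        min_cu = flat.min(axis=0)
    else:
        totals = flat.mean(axis=1)
        max_cu = flat[int(np.argmax(totals))].copy()
        min_cu = flat[int(np.argmin(totals))].copy()
    return SpectralProfile(cube.wavelengths_nm.copy(), max_cu, mean_cu, min_cu)


def band_index(wavelengths_nm: np.ndarray | HyperCube, lambda_nm: float) -> int:
    """Index of the band nearest ``lambda_nm``; ties go to the lower index.

    ``lambda_nm`` must lie within the grid's [first, last] range.
    """
    if isinstance(wavelengths_nm, HyperCube):
        wavelengths_nm = wavelengths_nm.wavelengths_nm
    wl = np.asarray(wavelengths_nm, dtype=float)
    if not (wl[0] <= lambda_nm <= wl[-1]):
        raise ValueError(
            f"wavelength {lambda_nm} nm outside grid range [{wl[0]}, {wl[-1]}] nm"
        )
    return int(np.argmin(np.abs(wl - lambda_nm)))


def band_metrics(profile: SpectralProfile, lambda_nm: float = DEFAULT_LAMBDA_NM) -> BandMetrics:
    """Mean reflectance and max−min range at the band nearest ``lambda_nm``."""
    k = band_index(profile.wavelengths_nm, lambda_nm)
    return BandMetrics(
        lambda_nm=float(profile.wavelengths_nm[k]),
        mean_cu=float(profile.mean_cu[k]),
        range_cu=float(profile.max_cu[k] - profile.min_cu[k]),
    )
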