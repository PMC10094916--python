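"""Gray-level conversion and GLCM texture statistics.

The gray-level co-occurrence matrix (GLCM) tabulates how often a pixel of
gray level *i* has a neighbour of level *j* at a fixed offset.  Here the
offset defaults to the immediate right neighbour (distance d = 1, angle
θ = 0°) and pairs are counted *ordered* (asymmetric matrix): entry (i, j)
is the frequency with which a pixel of level j sits directly to the right
of a pixel of level i.  The two texture statistics are

    contrast    = Σ_{i,j} (i − j)²  p(i, j)
    homogeneity = Σ_{i,j} p(i, j) / (1 + |i − j|)

which are 0 and 1 respectively exactly when every neighbour pair is equal.
Because both are functions of |i − j| only, symmetrising the matrix does
not change them; a symmetric option is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envi import ROI, HyperCube

__all__ = [
    "GLCMParams",
    "GrayImage",
    "CooccurrenceMatrix",
    "TextureMetrics",
    "cube_to_gray",
    "glcm",
    "glcm_contrast",
    "glcm_homogeneity",
    "brightness",
    "texture_metrics",
    "round_half_up",
]

# (Δcol, Δrow) offsets for the four standard GLCM directions.  θ = 0° is the
# neighbour directly to the right; rows grow downward so 45° points up-right.
_OFFSETS = {0: (1, 0), 45: (1, -1), 90: (0, -1), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMParams:
    """Offset and quantisation parameters for co-occurrence counting."""

    d: int = 1
    theta_deg: int = 0
    levels: int = 256
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("distance d must be >= 1")
        if self.theta_deg not in _OFFSETS:
            raise ValueError(f"theta must be one of {sorted(_OFFSETS)}, got {self.theta_deg}")
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")

    @property
    def offset(self) -> tuple[int, int]:
        """(Δcol, Δrow) displacement of the neighbour pixel."""
        dx, dy = _OFFSETS[self.theta_deg]
        return dx * self.d, dy * self.d


@dataclass
class GrayImage:
    """2-D integer image with levels in [0, levels-1]."""

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("gray image must be 2-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("gray image must hold integers")
        if self.pixels.size < 2:
            raise ValueError("gray image must have at least two pixels")
        if self.pixels.min() < 0 or self.pixels.max() >= self.levels:
            raise ValueError(f"gray values must lie in [0, {self.levels - 1}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CooccurrenceMatrix:
    """Normalised pair-frequency matrix p(i, j), Σ p = 1."""

    p: np.ndarray
    params: GLCMParams = field(default_factory=GLCMParams)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(self.p < 0):
            raise ValueError("co-occurrence frequencies must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"co-occurrence matrix must sum to 1, got {self.p.sum()!r}")


@dataclass(frozen=True)
class TextureMetrics:
    brightness: float
    contrast: float
    homogeneity: float


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round with exact halves going up (0.5 -> 1), unlike banker's rounding."""
    return np.floor(np.asarray(x) + 0.5)


def cube_to_gray(cube: HyperCube, roi: ROI, levels: int = 256) -> GrayImage:
    """Quantise a calibrated ROI to gray levels via the band-mean reflectance.

    Each pixel's "total reflectance" is the unweighted mean of its spectrum;
    the gray level is ``round_half_up((levels-1) * total / scale_cu)`` clipped
    into range.  Requires a calibrated cube.
    """
    if not cube.calibrated:
        raise ValueError("cube must be calibrated before gray conversion")
    total = roi.extract(cube).mean(axis=2)
    gray = round_half_up((levels - 1) * total / cube.scale_cu)
    gray = np.clip(gray, 0, levels - 1).astype(np.int64)
    return GrayImage(gray, levels=levels)


def glcm(img: GrayImage, params: GLCMParams | None = None) -> CooccurrenceMatrix:
    """Co-occurrence matrix of (pixel, offset-neighbour) ordered pairs.

    Counts every in-bounds pair (pixel at (r, c), pixel at (r+Δrow, c+Δcol)),
    optionally adds the transposed counts (symmetric mode), and normalises
    to probabilities.
    """
    params = params or GLCMParams(levels=img.levels)
    if params.levels != img.levels:
        raise ValueError("GLCM level count must match the image")
    dx, dy = params.offset
    rows, cols = img.shape
    px = img.pixels
    # slice the source/neighbour windows for the (dx, dy) displacement
    r0, r1 = max(0, -dy), min(rows, rows - dy)
    c0, c1 = max(0, -dx), min(cols, cols - dx)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"image {rows}x{cols} has no pixel pair at offset {(dx, dy)}")
    src = px[r0:r1, c0:c1].ravel()
    dst = px[r0 + dy : r1 + dy, c0 + dx : c1 + dx].ravel()
    G = params.levels
    counts = np.bincount(src * G + dst, minlength=G * G).reshape(G, G).astype(float)
    if params.symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(counts / counts.sum(), params=params)


def _level_differences(G: int) -> np.ndarray:
    i = np.arange(G)
    return i[:, None] - i[None, :]


def glcm_contrast(m: CooccurrenceMatrix) -> float:
    """Σ (i−j)² p(i,j); 0 iff all offset-neighbour pairs are equal."""
    diff = _level_differences(m.p.shape[0])
    return float((diff.astype(float) ** 2 * m.p).sum())


def glcm_homogeneity(m: CooccurrenceMatrix) -> float:
    """Σ p(i,j)/(1+|i−j|); 1 iff all offset-neighbour pairs are equal."""
    diff = np.abs(_level_differences(m.p.shape[0]))
    return float((m.p / (1.0 + diff)).sum())


def brightness(img: GrayImage) -> float:
    """Arithmetic mean gray level of the image."""
    return float(img.pixels.mean())


def texture_metrics(cube: HyperCube, roi: ROI,
                    params: GLCMParams | None = None) -> TextureMetrics:
    """Brightness, GLCM contrast and GLCM homogeneity of a cube ROI."""
    params = params or GLCMParams()
    img = cube_to_gray(cube, roi, levels=params.levels)
    m = glcm(img, params)
    return TextureMetrics(
        brightness=brightness(img),
        contrast=glcm_contrast(m),
        homogeneity=glcm_homogeneity(m),
    )
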