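"""Synthetic paired-cohort generator with prescribed texture statistics.

The generator works backwards from the analysis: for a texture whose
horizontal neighbour differences ``e`` are drawn from a symmetric integer
step distribution, the asymmetric right-neighbour GLCM gives exactly

    contrast    = E[e²]
    homogeneity = E[1 / (1 + |e|)]

so a (contrast, homogeneity) target pair is inverted into a three-level
step distribution on support {0, ±1, ±m2} (:func:`solve_step_distribution`),
a gray image is laid out whose neighbour-difference multiset realises that
distribution with steps paired +e/−e so levels stay in a narrow corridor
around the brightness target (:func:`pattern_synthesize`), and the image is
lifted to a reflectance cube by giving every pixel one shared smooth
skin-like spectral shape scaled in proportion to its gray level — a
melanin-like model in which darker pixels reflect uniformly less — globally
rescaled so the ROI-mean reflectance at the analysis band hits its target
(:func:`gray_to_cube`).

The packaged "paper-cohort" preset is a deterministic 12-patient target
table designed so that the cohort summaries of the targets reproduce a
fixed set of printed study statistics (means, SDs, medians, direction
counts) simultaneously; :func:`design_paper_preset` rebuilds it from
scratch and :func:`paper_preset` loads the frozen copy shipped with the
package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .envi import (
    DEFAULT_SCALE_CU,
    ROI,
    CohortManifest,
    HyperCube,
    default_wavelength_grid,
    write_envi,
    write_manifest,
)
from .spectra import DEFAULT_LAMBDA_NM, band_index
from .texture import GrayImage

__all__ = [
    "StepDistribution",
    "PatientTargets",
    "CohortPreset",
    "InfeasibleTargetsError",
    "SynthesisParameterError",
    "solve_step_distribution",
    "pattern_synthesize",
    "gray_to_cube",
    "design_paper_preset",
    "paper_preset",
    "build_cohort",
    "validate_preset",
]

#: m2 candidates for the three-level support; 8 first (widest headroom for
#: skin-like contrast/homogeneity pairs), then the rest of the small grid.
_M2_GRID = (8,) + tuple(m for m in range(2, 17) if m != 8)

#: raw counts per c.u. when cubes are written to disk as 16-bit integers
_RAW_GAIN = 16


class InfeasibleTargetsError(ValueError):
    """No symmetric three-level step distribution matches the moment pair."""


class SynthesisParameterError(ValueError):
    """Targets cannot be laid out within the gray-level range."""


@dataclass
class StepDistribution:
    """Symmetric, zero-mean distribution over integer neighbour steps."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape or self.support.ndim != 1:
            raise ValueError("support and probs must be matching 1-D arrays")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        # symmetry: P(e) == P(-e)
        lookup = dict(zip(self.support.tolist(), self.probs.tolist()))
        for e, p in lookup.items():
            if abs(p - lookup.get(-e, 0.0)) > 1e-9:
                raise ValueError("step distribution must be symmetric")

    def contrast(self) -> float:
        """E[e²] — the GLCM contrast a texture with these steps realises."""
        return float(np.sum(self.probs * self.support.astype(float) ** 2))

    def homogeneity(self) -> float:
        """E[1/(1+|e|)] — the GLCM homogeneity such a texture realises."""
        return float(np.sum(self.probs / (1.0 + np.abs(self.support))))

    def magnitude_probs(self) -> dict[int, float]:
        """P(|e| = m) for each nonzero magnitude m in the support."""
        out: dict[int, float] = {}
        for e, p in zip(self.support, self.probs):
            if e != 0:
                out[abs(int(e))] = out.get(abs(int(e)), 0.0) + float(p)
        return out

    @property
    def p_zero(self) -> float:
        zero = self.support == 0
        return float(self.probs[zero].sum()) if zero.any() else 0.0


def solve_step_distribution(contrast_target: float, homogeneity_target: float,
                            m2_grid: tuple[int, ...] = _M2_GRID) -> StepDistribution:
    """Invert (contrast, homogeneity) into a step distribution on {0, ±1, ±m2}.

    With magnitude probabilities p0, p1, p2 the moment equations are

        p1 + m2² p2              = contrast
        p0 + p1/2 + p2/(1+m2)    = homogeneity,   p0 + p1 + p2 = 1

    a linear 2×2 system in (p1, p2) for each candidate m2; the first m2 in
    the grid yielding probabilities in [0, 1] wins.  Raises
    :class:`InfeasibleTargetsError` when no candidate works (necessarily so
    when contrast < 2·(1−homogeneity) or exactly one of the targets is
    degenerate).
    """
    c, h = float(contrast_target), float(homogeneity_target)
    if not (0.0 < h <= 1.0) or c < 0.0:
        raise InfeasibleTargetsError(f"targets outside range: contrast={c}, homogeneity={h}")
    if c == 0.0:
        if h != 1.0:
            raise InfeasibleTargetsError("zero contrast forces homogeneity 1")
        return StepDistribution(np.array([0]), np.array([1.0]))
    for m2 in m2_grid:
        denom = m2 * m2 - 2.0 * m2 / (1.0 + m2)
        p2 = (c - 2.0 * (1.0 - h)) / denom
        p1 = 2.0 * (1.0 - h) - (2.0 * m2 / (1.0 + m2)) * p2
        p0 = 1.0 - p1 - p2
        eps = 1e-12
        if p1 < -eps or p2 < -eps or p0 < -eps:
            continue
        p0, p1, p2 = max(p0, 0.0), max(p1, 0.0), max(p2, 0.0)
        support = [-m2, -1, 0, 1, m2]
        probs = [p2 / 2, p1 / 2, p0, p1 / 2, p2 / 2]
        return StepDistribution(np.array(support), np.array(probs))
    raise InfeasibleTargetsError(
        f"no three-level support in the m2 grid fits contrast={c}, homogeneity={h}"
    )


# --------------------------------------------------------------------------
# Texture synthesis


def _step_counts(dist: StepDistribution, n_pairs: int) -> dict[int, int]:
    """Round magnitude probabilities to integer step counts over n_pairs slots."""
    counts: dict[int, int] = {}
    for m, p in sorted(dist.magnitude_probs().items()):
        counts[m] = int(round(p * n_pairs))
    overflow = sum(counts.values()) - n_pairs
    if overflow > 0:  # take the excess out of the most frequent magnitude
        biggest = max(counts, key=counts.get)
        counts[biggest] -= overflow
        if counts[biggest] < 0:
            raise SynthesisParameterError("step counts exceed available pairs")
    return {m: n for m, n in counts.items() if n > 0}


def pattern_synthesize(brightness_target: float, dist: StepDistribution,
                       shape: tuple[int, int] = (64, 64), seed: int = 0,
                       levels: int = 256) -> GrayImage:
    """Lay out a gray image realising the step distribution moment-exactly.

    Each row is a level sequence whose consecutive differences are drawn
    from the rounded step multiset, with +e and −e emitted adjacently so
    partial sums stay in a bounded corridor; the remaining freedom (unit
    order, which rows sit one level higher) is shuffled by ``seed``.  The
    measured brightness is within ±0.5 gray level of the target, and the
    measured contrast and homogeneity equal the rounded multiset's moments
    E[e²] and E[1/(1+|e|)] exactly under the asymmetric right-neighbour
    count.
    """
    rows, cols = shape
    if rows < 1 or cols < 2:
        raise SynthesisParameterError("need at least 1x2 pixels")
    if not (0.0 <= brightness_target <= levels - 1):
        raise SynthesisParameterError("brightness target outside gray range")
    n_pairs = rows * (cols - 1)
    counts = _step_counts(dist, n_pairs)
    rng = np.random.default_rng(seed)

    # units: ('pair', e) occupies two step slots (+e then −e), ('single', e)
    # and ('zero', 0) occupy one
    units: list[tuple[str, int]] = []
    singles: list[int] = []
    for m, n in counts.items():
        units.extend([("pair", m)] * (n // 2))
        if n % 2:
            singles.append(m)
    rng.shuffle(units)

    free = np.full(rows, cols - 1, dtype=int)
    row_units: list[list[tuple[str, int]]] = [[] for _ in range(rows)]
    r = 0
    for unit in units:
        placed = False
        for _ in range(rows):
            if free[r] >= 2:
                row_units[r].append(unit)
                free[r] -= 2
                placed = True
                r = (r + 1) % rows
                break
            r = (r + 1) % rows
        if not placed:  # only rows with one free slot left: split the pair
            singles.extend([unit[1], -unit[1]])
    for s in singles:
        candidates = np.flatnonzero(free >= 1)
        if candidates.size == 0:
            raise SynthesisParameterError("step multiset does not fit the image")
        rr = int(candidates[rng.integers(candidates.size)])
        row_units[rr].append(("single", s))
        free[rr] -= 1
    for rr in range(rows):
        row_units[rr].extend([("zero", 0)] * free[rr])

    profile = np.empty((rows, cols), dtype=np.int64)
    for rr in range(rows):
        order = rng.permutation(len(row_units[rr]))
        steps: list[int] = []
        for idx in order:
            kind, e = row_units[rr][idx]
            if kind == "pair":
                steps.extend([e, -e])
            elif kind == "single":
                steps.append(e)
            else:
                steps.append(0)
        lvl = np.concatenate([[0], np.cumsum(steps)])
        profile[rr] = lvl - lvl.min()

    delta = profile.mean()
    base = np.floor(brightness_target - delta)
    if base < 0:
        raise SynthesisParameterError(
            "brightness target too low for the step corridor; use a smaller m2 "
            "or recenter the brightness"
        )
    frac = brightness_target - delta - base
    k = int(round(frac * rows))
    bump_rows = rng.permutation(rows)[:k]
    bases = np.full(rows, int(base), dtype=np.int64)
    bases[bump_rows] += 1
    img = profile + bases[:, None]
    if img.max() > levels - 1:
        raise SynthesisParameterError(
            "step corridor exceeds the gray range; use a smaller m2 or recenter "
            "the brightness"
        )
    return GrayImage(img, levels=levels)


# --------------------------------------------------------------------------
# Spectral lifting


def _base_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth skin-like reflectance shape: low in the blue-green (strong
    melanin/haemoglobin absorption), rising through the red, normalised to
    band-mean 1."""
    s = 0.35 + 1.25 / (1.0 + np.exp(-(wavelengths - 580.0) / 40.0))
    return s / s.mean()


def gray_to_cube(img: GrayImage, refl_mean_target_cu: float,
                 wavelengths: np.ndarray | None = None, seed: int = 0,
                 noise_sd_cu: float = 0.0, lambda_nm: float = DEFAULT_LAMBDA_NM,
                 scale_cu: float = DEFAULT_SCALE_CU) -> HyperCube:
    """Lift a gray image to a calibrated reflectance cube.

    Every pixel receives one shared smooth spectral shape scaled by
    ``scale_cu · g / (levels−1)`` — so brighter pixels reflect pointwise
    more and the band-mean reflectance reproduces the gray level exactly —
    and the shape itself is adjusted (unit band-mean, prescribed value at
    the analysis band) so that the image-mean reflectance at the band
    nearest ``lambda_nm`` equals ``refl_mean_target_cu``.  Optional
    zero-mean Gaussian noise (``noise_sd_cu``) is seeded and clipped at 0.
    """
    if wavelengths is None:
        wavelengths = default_wavelength_grid()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (0.0 <= refl_mean_target_cu <= scale_cu):
        raise SynthesisParameterError(
            f"reflectance target {refl_mean_target_cu} outside [0, {scale_cu}]"
        )
    k = band_index(wavelengths, lambda_nm)
    mg = img.pixels.mean()
    scale_per_level = scale_cu / (img.levels - 1)
    if mg == 0:
        if refl_mean_target_cu != 0:
            raise SynthesisParameterError("all-black image cannot hit a nonzero target")
        data = np.zeros(img.shape + (len(wavelengths),))
        return HyperCube(data, wavelengths, calibrated=True, scale_cu=scale_cu)

    # shape s with mean(s) = 1 and s[k] chosen so the ROI mean at band k
    # equals the target: mean_pixels(scale_per_level * g) * s[k] = target
    s_k = refl_mean_target_cu / (scale_per_level * mg)
    s0 = _base_shape(wavelengths)
    bump = np.exp(-((wavelengths - wavelengths[k]) ** 2) / (2.0 * 30.0**2))
    # solve a*s0 + b*bump for mean 1 and value s_k at band k
    A = np.array([[1.0, bump.mean()], [s0[k], bump[k]]])
    a, b = np.linalg.solve(A, np.array([1.0, s_k]))
    s = a * s0 + b * bump
    if np.any(s <= 0):
        raise SynthesisParameterError(
            "reflectance target too far from the skin-like spectral shape"
        )
    data = (scale_per_level * img.pixels.astype(float))[:, :, None] * s[None, None, :]
    if noise_sd_cu > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_cu, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    return HyperCube(data, wavelengths, calibrated=True, scale_cu=scale_cu)


# --------------------------------------------------------------------------
# Cohort presets


@dataclass(frozen=True)
class PatientTargets:
    """Per-patient before/after targets for the four measured quantities."""

    patient_id: str
    brightness_b: float
    brightness_a: float
    contrast_b: float
    contrast_a: float
    homogeneity_b: float
    homogeneity_a: float
    refl654_b: float
    refl654_a: float

    def __post_init__(self) -> None:
        for phase in "ba":
            br = getattr(self, f"brightness_{phase}")
            co = getattr(self, f"contrast_{phase}")
            ho = getattr(self, f"homogeneity_{phase}")
            re = getattr(self, f"refl654_{phase}")
            if not (0 <= br <= 255):
                raise ValueError(f"brightness target {br} outside [0, 255]")
            if co < 0:
                raise ValueError("contrast target must be >= 0")
            if not (0 < ho <= 1):
                raise ValueError(f"homogeneity target {ho} outside (0, 1]")
            if not (0 <= re <= DEFAULT_SCALE_CU):
                raise ValueError(f"reflectance target {re} outside [0, scale]")


@dataclass
class CohortPreset:
    """A named cohort of patient targets plus cube geometry and seed."""

    name: str
    patients: list[PatientTargets]
    rows: int = 64
    cols: int = 64
    bands: int = 204
    wl_start_nm: float = 400.0
    wl_step_nm: float = 2.941
    lambda_nm: float = DEFAULT_LAMBDA_NM
    seed: int = 20230

    def wavelengths(self) -> np.ndarray:
        return default_wavelength_grid(self.bands, self.wl_start_nm, self.wl_step_nm)

    _COLUMNS = ("patient_id", "brightness_b", "brightness_a", "contrast_b",
                "contrast_a", "homogeneity_b", "homogeneity_a", "refl654_b",
                "refl654_a")

    def to_text(self) -> str:
        lines = [
            f"# name: {self.name}",
            f"# seed: {self.seed}",
            f"# shape: {self.rows} {self.cols} {self.bands}",
            f"# grid_nm: {self.wl_start_nm} {self.wl_step_nm}",
            f"# lambda_nm: {self.lambda_nm}",
            ",".join(self._COLUMNS),
        ]
        for p in self.patients:
            vals = [p.patient_id] + [
                f"{getattr(p, c):.6f}" for c in self._COLUMNS[1:]
            ]
            lines.append(",".join(vals))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CohortPreset":
        meta: dict[str, str] = {}
        rows: list[PatientTargets] = []
        header_seen = False
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if tuple(line.split(",")) != cls._COLUMNS:
                    raise ValueError(f"unexpected preset header: {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            rows.append(PatientTargets(parts[0], *(float(v) for v in parts[1:])))
        if not rows:
            raise ValueError("preset has no patient rows")
        shape = meta.get("shape", "64 64 204").split()
        grid = meta.get("grid_nm", "400.0 2.941").split()
        return cls(
            name=meta.get("name", "unnamed"),
            patients=rows,
            rows=int(shape[0]), cols=int(shape[1]), bands=int(shape[2]),
            wl_start_nm=float(grid[0]), wl_step_nm=float(grid[1]),
            lambda_nm=float(meta.get("lambda_nm", DEFAULT_LAMBDA_NM)),
            seed=int(meta.get("seed", 20230)),
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CohortPreset":
        with open(os.fspath(path), "r") as fh:
            return cls.from_text(fh.read())


# -- the packaged 12-patient study-statistics preset ------------------------

# Cohort constraints the design must satisfy simultaneously (the printed
# study statistics the synthetic cohort stands in for):
PAPER_CONSTRAINTS = {
    "brightness": dict(mean_b=143.33, sd_b=23.75, mean_a=157.67, sd_a=19.89,
                       median_diff=15.50, n_increase=9),
    "contrast": dict(mean_b=5.86, sd_b=1.09, mean_a=5.21, sd_a=1.06,
                     n_decrease=10),
    "homogeneity": dict(mean_b=0.56, sd_b=0.16, mean_a=0.64, sd_a=0.13,
                        n_increase=8),
    "refl654": dict(median_b=854.0, median_a=932.0),
}

# Designed after-minus-before difference vectors, in patient order.  Each has
# the required direction counts, sums to n·(mean_after − mean_before), and —
# for brightness — middle order statistics pinned at the required median.
_BRIGHTNESS_DIFFS = [15.5, -4.0, 22.0, 8.0, 37.08, 12.0, -2.0, 26.0, 15.5, 30.0, -6.0, 18.0]
_CONTRAST_DIFFS = [-0.6, 0.3, -1.0, -0.35, -1.9, -0.2, 0.15, -0.8, -0.5, -1.3, -0.7, -0.9]
_HOMOGENEITY_DIFFS = [0.10, -0.02, 0.14, 0.05, 0.22, 0.08, -0.01, 0.16, 0.12, 0.19, -0.04, -0.03]

# Before/after reflectance at the 654 nm band, c.u.; middle order statistics
# pinned at the required medians, every patient increasing.
_REFL_BEFORE = [854.0, 793.0, 893.0, 830.0, 966.0, 846.0, 760.0, 912.0, 854.0, 938.0, 815.0, 871.0]
_REFL_AFTER = [932.0, 869.0, 961.0, 914.0, 1012.0, 926.0, 841.0, 983.0, 932.0, 998.0, 890.0, 947.0]


def _paired_values(mean_b: float, sd_b: float, mean_a: float, sd_a: float,
                   diffs: np.ndarray, resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Before/after vectors with exact means/SDs and the given differences.

    The before vector is an affine combination of the standardised
    difference pattern and an orthogonalised residual pattern; the mixing
    weight is the correlation forced by var(after) = var(before) + var(d)
    + 2 cov(before, d).
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if abs(d.sum() - n * (mean_a - mean_b)) > 1e-9:
        raise ValueError("difference vector does not bridge the two means")
    sd_d = d.std(ddof=1)
    rho = (sd_a**2 - sd_b**2 - sd_d**2) / (2.0 * sd_b * sd_d)
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"required before/difference correlation {rho} infeasible")
    dz = (d - d.mean()) / sd_d
    w = resid - resid.mean()
    w = w - dz * (w @ dz) / (dz @ dz)
    w = w / w.std(ddof=1)
    z = rho * dz + np.sqrt(1.0 - rho * rho) * w
    before = mean_b + sd_b * z
    return before, before + d


def _is_feasible(contrast: float, homogeneity: float) -> bool:
    try:
        solve_step_distribution(contrast, homogeneity)
        return True
    except InfeasibleTargetsError:
        return False


def design_paper_preset(seed: int = 20230) -> CohortPreset:
    """Construct the 12-patient preset satisfying ``PAPER_CONSTRAINTS``.

    The difference vectors and reflectance medians are fixed design
    choices; the residual patterns that spread the before-phase values are
    drawn from a seeded generator and searched deterministically until all
    side conditions hold.  Low homogeneity is only realisable together with
    high contrast (pushing homogeneity down takes many large gray-level
    steps, which drive contrast up — the two statistics are negatively
    coupled), so the per-metric patient columns are re-paired by sorting:
    the lowest-homogeneity patient receives the highest contrast.  The
    result is validated against every constraint before being returned.
    """
    rng = np.random.default_rng(987654321)
    cons = PAPER_CONSTRAINTS

    def attempt(metric: str, diffs: list[float], accept) -> tuple[np.ndarray, np.ndarray]:
        c = cons[metric]
        for _ in range(500):
            try:
                b, a = _paired_values(c["mean_b"], c["sd_b"], c["mean_a"],
                                      c["sd_a"], np.array(diffs),
                                      rng.standard_normal(12))
            except ValueError:
                continue
            if accept(b, a):
                return b, a
        raise InfeasibleTargetsError(f"no acceptable {metric} pattern found")

    br_b, br_a = attempt(
        "brightness", _BRIGHTNESS_DIFFS,
        lambda b, a: b.min() > 40 and a.min() > 40 and b.max() < 230 and a.max() < 230,
    )
    co_b, co_a = attempt(
        "contrast", _CONTRAST_DIFFS,
        lambda b, a: b.min() > 1.0 and a.min() > 1.0,
    )

    # homogeneity, jointly feasible with the contrast pairs after sorting
    order_c = np.argsort(-co_b)  # contrast pairs, highest first
    c_ho = cons["homogeneity"]
    for _ in range(2000):
        try:
            ho_b, ho_a = _paired_values(
                c_ho["mean_b"], c_ho["sd_b"], c_ho["mean_a"], c_ho["sd_a"],
                np.array(_HOMOGENEITY_DIFFS), rng.standard_normal(12))
        except ValueError:
            continue
        if not (0.05 < ho_b.min() and ho_b.max() <= 1.0
                and 0.05 < ho_a.min() and ho_a.max() <= 1.0):
            continue
        order_h = np.argsort(ho_b)  # homogeneity pairs, lowest first
        if all(
            _is_feasible(co_b[order_c[i]], ho_b[order_h[i]])
            and _is_feasible(co_a[order_c[i]], ho_a[order_h[i]])
            for i in range(12)
        ):
            break
    else:
        raise InfeasibleTargetsError("no jointly feasible homogeneity pattern found")

    patients = [
        PatientTargets(
            patient_id=f"P{i + 1:02d}",
            brightness_b=round(br_b[i], 6), brightness_a=round(br_a[i], 6),
            contrast_b=round(co_b[order_c[i]], 6),
            contrast_a=round(co_a[order_c[i]], 6),
            homogeneity_b=round(ho_b[order_h[i]], 6),
            homogeneity_a=round(ho_a[order_h[i]], 6),
            refl654_b=_REFL_BEFORE[i], refl654_a=_REFL_AFTER[i],
        )
        for i in range(12)
    ]
    preset = CohortPreset(name="paper-cohort", patients=patients, seed=seed)
    validate_preset(preset)
    return preset


def validate_preset(preset: CohortPreset, atol: float = 0.005) -> None:
    """Check the preset's target table against ``PAPER_CONSTRAINTS``.

    Verifies means/SDs to ``atol``, the pinned medians, every direction
    count, and that each (contrast, homogeneity) pair is feasible for the
    step-distribution solver.  Raises ``AssertionError`` on violation.
    """
    cons = PAPER_CONSTRAINTS

    def col(name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in preset.patients])

    for metric in ("brightness", "contrast", "homogeneity"):
        b, a = col(f"{metric}_b"), col(f"{metric}_a")
        c = cons[metric]
        assert abs(b.mean() - c["mean_b"]) < atol, f"{metric} before mean"
        assert abs(b.std(ddof=1) - c["sd_b"]) < atol, f"{metric} before sd"
        assert abs(a.mean() - c["mean_a"]) < atol, f"{metric} after mean"
        assert abs(a.std(ddof=1) - c["sd_a"]) < atol, f"{metric} after sd"
        d = a - b
        if "n_increase" in c:
            assert int((d > 0).sum()) == c["n_increase"], f"{metric} increases"
        if "n_decrease" in c:
            assert int((d < 0).sum()) == c["n_decrease"], f"{metric} decreases"
        if "median_diff" in c:
            assert abs(np.median(d) - c["median_diff"]) < atol, f"{metric} median diff"
    rb, ra = col("refl654_b"), col("refl654_a")
    assert abs(np.median(rb) - cons["refl654"]["median_b"]) < atol
    assert abs(np.median(ra) - cons["refl654"]["median_a"]) < atol
    for p in preset.patients:
        solve_step_distribution(p.contrast_b, p.homogeneity_b)
        solve_step_distribution(p.contrast_a, p.homogeneity_a)


def paper_preset() -> CohortPreset:
    """The frozen packaged paper-cohort preset table."""
    text = resources.files("hyperskin.data").joinpath("paper_cohort.csv").read_text()
    return CohortPreset.from_text(text)


# --------------------------------------------------------------------------
# Cohort building


def build_cohort(preset: CohortPreset, out_dir: str | os.PathLike,
                 seed: int | None = None, noise_sd_cu: float = 0.0) -> str:
    """Synthesize and write the full before/after cohort as ENVI files.

    For each patient and phase: invert the texture targets into a step
    distribution, lay out the gray image, lift it to a reflectance cube,
    convert to raw 16-bit counts under a flat lamp and write the ENVI
    pair.  A constant white-reference cube and the cohort manifest are
    written alongside.  Fully deterministic for a given seed (defaults to
    the preset's own).

    Returns the manifest path.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    seed = preset.seed if seed is None else seed
    wavelengths = preset.wavelengths()
    roi = ROI(0, 0, preset.rows, preset.cols)
    white_level = int(round(_RAW_GAIN * DEFAULT_SCALE_CU))  # 16368 counts

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * len(preset.patients) * 2)
    patients: list[tuple[str, str, str, ROI]] = []
    si = 0
    for p in preset.patients:
        paths = {}
        for phase in ("b", "a"):
            dist = solve_step_distribution(
                getattr(p, f"contrast_{phase}"), getattr(p, f"homogeneity_{phase}")
            )
            img = pattern_synthesize(
                getattr(p, f"brightness_{phase}"), dist,
                shape=(preset.rows, preset.cols), seed=int(child_seeds[si] % 2**31),
            )
            cube = gray_to_cube(
                img, getattr(p, f"refl654_{phase}"), wavelengths,
                seed=int(child_seeds[si + 1] % 2**31), noise_sd_cu=noise_sd_cu,
                lambda_nm=preset.lambda_nm,
            )
            si += 2
            # to raw 16-bit counts under a spectrally flat lamp
            raw = np.rint(cube.data * (white_level / cube.scale_cu)).astype(np.uint16)
            raw_cube = HyperCube(raw, wavelengths, calibrated=False)
            phase_name = "before" if phase == "b" else "after"
            hdr = os.path.join(out_dir, f"{p.patient_id}_{phase_name}.hdr")
            write_envi(raw_cube, hdr, interleave="bil")
            paths[phase] = hdr
        patients.append((p.patient_id, paths["b"], paths["a"], roi))

    white = HyperCube(
        np.full((16, 16, preset.bands), white_level, dtype=np.uint16),
        wavelengths, calibrated=False,
    )
    white_hdr = os.path.join(out_dir, "white_reference.hdr")
    write_envi(white, white_hdr, interleave="bil")

    manifest = CohortManifest(patients=patients, white_path=white_hdr)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    write_manifest(manifest, manifest_path)
    return manifest_path
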