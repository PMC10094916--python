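"""End-to-end cohort analysis: manifest -> per-patient metrics -> summary.

Ties the modules together the way a study run uses them: read each
patient's before/after raw cubes, calibrate against the shared white
reference, compute the texture metrics (brightness, GLCM contrast, GLCM
homogeneity) and the absorption-band spectral metrics, then aggregate the
paired records into the cohort summary and write the report files.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .cohort import CohortSummary, PatientRecord, report, summarize
from .envi import DEFAULT_SCALE_CU, CohortManifest, HyperCube, calibrate, read_envi, read_manifest
from .spectra import DEFAULT_LAMBDA_NM, SpectralProfile, band_metrics, roi_profiles
from .texture import GLCMParams, cube_to_gray, texture_metrics

__all__ = ["RunConfig", "AnalysisResult", "analyze_manifest", "analyze_cohort"]


@dataclass
class RunConfig:
    """Resolved analysis configuration, serialised verbatim into each run."""

    glcm_d: int = 1
    glcm_theta: int = 0
    levels: int = 256
    symmetric: bool = False
    lambda_nm: float = DEFAULT_LAMBDA_NM
    scale_cu: float = DEFAULT_SCALE_CU
    quantile_convention: str = "linear"
    seed: int = 0

    def glcm_params(self) -> GLCMParams:
        return GLCMParams(d=self.glcm_d, theta_deg=self.glcm_theta,
                          levels=self.levels, symmetric=self.symmetric)

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(os.fspath(path), "r") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class AnalysisResult:
    records: list[PatientRecord]
    summary: CohortSummary | None
    profiles: dict[tuple[str, str], SpectralProfile] = field(default_factory=dict)
    gray_images: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _load_calibrated(path: str, white: HyperCube | None,
                     config: RunConfig) -> HyperCube:
    cube = read_envi(path)
    if white is None:
        raise ValueError(
            f"manifest provides no white reference; cannot calibrate {path!r}"
        )
    return calibrate(cube, white, scale_cu=config.scale_cu)


def analyze_manifest(manifest_path: str | os.PathLike,
                     config: RunConfig | None = None) -> AnalysisResult:
    """Analyze every patient in a cohort manifest file."""
    return analyze_cohort(read_manifest(os.fspath(manifest_path)), config)


def analyze_cohort(manifest: CohortManifest,
                   config: RunConfig | None = None) -> AnalysisResult:
    """Per-patient texture + band metrics and the cohort summary.

    With fewer than two patients the per-patient records are still
    computed but the cohort summary is ``None`` (a single patient supports
    no paired cohort statistics).
    """
    import warnings

    config = config or RunConfig()
    params = config.glcm_params()
    white = read_envi(manifest.white_path) if manifest.white_path else None
    records: list[PatientRecord] = []
    profiles: dict[tuple[str, str], SpectralProfile] = {}
    grays: dict[tuple[str, str], np.ndarray] = {}
    for pid, before_path, after_path, roi in manifest.patients:
        phase_metrics = {}
        for phase, path in (("before", before_path), ("after", after_path)):
            try:
                cube = _load_calibrated(path, white, config)
            except Exception as exc:
                raise type(exc)(f"patient {pid} ({phase}): {exc}") from exc
            tm = texture_metrics(cube, roi, params)
            prof = roi_profiles(cube, roi)
            bm = band_metrics(prof, config.lambda_nm)
            phase_metrics[phase] = (tm, bm)
            profiles[(pid, phase)] = prof
            grays[(pid, phase)] = cube_to_gray(cube, roi, params.levels).pixels
        records.append(PatientRecord(
            patient_id=pid,
            before=phase_metrics["before"][0], after=phase_metrics["after"][0],
            before_band=phase_metrics["before"][1], after_band=phase_metrics["after"][1],
        ))
    if len(records) >= 2:
        summary = summarize(records)
    else:
        warnings.warn("fewer than 2 patients; skipping cohort statistics")
        summary = None
    return AnalysisResult(records=records, summary=summary, profiles=profiles,
                          gray_images=grays)


def write_run(result: AnalysisResult, config: RunConfig,
              out_dir: str | os.PathLike, plots: bool = True) -> None:
    """Write config, tables, profile exports and plots for a finished run."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    config.save(os.path.join(out_dir, "config.yaml"))
    if result.summary is not None:
        report(result.summary, out_dir, records=result.records)
    else:
        # still write the per-patient table so a 1-patient run is not empty
        _write_per_patient_only(result.records, out_dir)
    prof_dir = os.path.join(out_dir, "profiles")
    os.makedirs(prof_dir, exist_ok=True)
    for (pid, phase), prof in result.profiles.items():
        lines = ["wavelength_nm\tmax_cu\tmean_cu\tmin_cu"]
        for w, mx, me, mn in zip(prof.wavelengths_nm, prof.max_cu, prof.mean_cu, prof.min_cu):
            lines.append(f"{w:.3f}\t{mx:.4f}\t{me:.4f}\t{mn:.4f}")
        with open(os.path.join(prof_dir, f"{pid}_{phase}.tsv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
    if plots:
        _render_plots(result, out_dir)


def _write_per_patient_only(records, out_dir: str) -> None:
    lines = ["patient_id\tphase\tbrightness\tcontrast\thomogeneity\trefl_mean\trefl_range"]
    for r in records:
        for phase in ("before", "after"):
            tm = getattr(r, phase)
            bm = getattr(r, f"{phase}_band")
            lines.append(
                f"{r.patient_id}\t{phase}\t{tm.brightness:.6f}\t{tm.contrast:.6f}\t"
                f"{tm.homogeneity:.6f}\t{bm.mean_cu:.6f}\t{bm.range_cu:.6f}"
            )
    with open(os.path.join(out_dir, "per_patient.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _render_plots(result: AnalysisResult, out_dir: str) -> None:
    """Reflectance profile line charts per patient/phase pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = os.path.join(out_dir, "plots")
    os.makedirs(plot_dir, exist_ok=True)
    by_patient: dict[str, dict[str, SpectralProfile]] = {}
    for (pid, phase), prof in result.profiles.items():
        by_patient.setdefault(pid, {})[phase] = prof
    for pid, phases in by_patient.items():
        fig, axes = plt.subplots(1, len(phases), figsize=(5 * len(phases), 3.2),
                                 squeeze=False, sharey=True)
        for ax, (phase, prof) in zip(axes[0], sorted(phases.items())):
            ax.plot(prof.wavelengths_nm, prof.max_cu, color="tab:blue", label="max")
            ax.plot(prof.wavelengths_nm, prof.mean_cu, color="tab:red", label="mean")
            ax.plot(prof.wavelengths_nm, prof.min_cu, color="tab:green", label="min")
            ax.set_title(f"{pid} {phase}")
            ax.set_xlabel("wavelength (nm)")
            ax.set_ylabel("reflectance (c.u.)")
            ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(os.path.join(plot_dir, f"profiles_{pid}.png"), dpi=100)
        plt.close(fig)
    # 3-D brightness surfaces of the gray-converted ROI
    for (pid, phase), gray in result.gray_images.items():
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(111, projection="3d")
        rr, cc = np.meshgrid(np.arange(gray.shape[1]), np.arange(gray.shape[0]))
        ax.plot_surface(rr, cc, gray, cmap="viridis", linewidth=0)
        ax.set_title(f"{pid} {phase} brightness")
        ax.set_zlabel("gray level")
        fig.savefig(os.path.join(plot_dir, f"surface_{pid}_{phase}.png"), dpi=80)
        plt.close(fig)
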