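import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# --------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive; they are the
# reference the fast implementations are checked against)


def brute_glcm_counts(pixels: np.ndarray, levels: int, dx: int, dy: int,
                      symmetric: bool = False) -> np.ndarray:
    """Count (pixel, neighbour) ordered pairs by looping over every pixel."""
    rows, cols = pixels.shape
    counts = np.zeros((levels, levels), dtype=float)
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[pixels[r, c], pixels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def brute_contrast(p: np.ndarray) -> float:
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            total += (i - j) ** 2 * p[i, j]
    return total


def brute_homogeneity(p: np.ndarray) -> float:
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            total += p[i, j] / (1 + abs(i - j))
    return total


def brute_wilcoxon_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^m sign vectors."""
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    m = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_plus_obs = ranks[diffs > 0].sum()
    w_obs = min(w_plus_obs, ranks[diffs < 0].sum())
    w_plus_all = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=m)
    ])
    tail_low = np.mean(w_plus_all <= w_plus_obs + 1e-12)
    tail_high = np.mean(w_plus_all >= w_plus_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(tail_low, tail_high))


# --------------------------------------------------------------------------
# Shared fixtures


@pytest.fixture
def tiny_preset():
    """A fast 2-patient preset on full-size band grid (small spatial dims)."""
    from hyperskin.simulate import CohortPreset, PatientTargets

    return CohortPreset(
        name="tiny",
        patients=[
            PatientTargets("A", 120.0, 140.0, 2.0, 1.5, 0.70, 0.78, 600.0, 700.0),
            PatientTargets("B", 150.0, 145.0, 3.0, 3.2, 0.60, 0.58, 820.0, 800.0),
        ],
        rows=24, cols=24, bands=204, seed=7,
    )


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """The packaged paper cohort, built and analyzed once per session."""
    from hyperskin.pipeline import analyze_manifest
    from hyperskin.simulate import build_cohort, paper_preset

    preset = paper_preset()
    out = tmp_path_factory.mktemp("paper_cohort")
    manifest = build_cohort(preset, out)
    result = analyze_manifest(manifest)
    return preset, result
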