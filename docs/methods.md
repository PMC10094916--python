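# Methods

This note documents the measurement model the package implements, the
conventions that are test-visible, what the synthetic cohort does and does
not emulate, and the design decisions that were genuinely open.

## Measurement chain

**Cubes and calibration.** A hyperspectral cube is a `(row, col, band)`
array with one wavelength per band (default grid: 204 bands at
400 + k·2.941 nm, modelling a 400–1000 nm push-broom camera with ~2.9 nm
resolution and 512×512 spatial frames). Raw counts are converted to
reflectance per band as

    R = scale_cu · (raw − dark) / (white − dark)

where the white (and optional dark) reference cubes are spatially averaged
to one spectrum each before division. The dark reference defaults to zero
— consumer workflows frequently omit it — and values falling below zero
after dark subtraction are clipped to zero (sensor noise), not treated as
errors. Reflectance is carried in *counts-units* (c.u.) with
`scale_cu = 1023` (a 10-bit-like scale) corresponding to 100 % reflectance;
the scale is configurable. All coordinates are 0-based half-open, stated
once and used everywhere.

**Gray conversion.** The texture analysis needs a scalar per pixel. Each
pixel's *total reflectance* is the unweighted mean of its spectrum (no
spectral weighting: none is better motivated, and the choice is declared
rather than hidden), and the gray level is

    g = round_half_up((G−1) · total / scale_cu),  G = 256.

Round-half-up is stated explicitly because it is observable at exact
midpoints (band-mean 511.5 → level 128). G = 256 matches the 0–255 range
the brightness statistics live on.

**GLCM statistics.** The co-occurrence matrix counts *ordered* pairs
(pixel, pixel directly to its right) — distance d = 1, angle θ = 0°,
asymmetric by default; a symmetric option exists but both reported
statistics are functions of |i−j| and are unaffected by symmetrisation.
Contrast `Σ(i−j)²p(i,j)` and homogeneity `Σp(i,j)/(1+|i−j|)` satisfy the
boundary theorem: contrast = 0 ⇔ homogeneity = 1 ⇔ every neighbour pair is
equal. Note the homogeneity weight here is `1/(1+|i−j|)`; some libraries
(e.g. scikit-image's `graycoprops`) use the inverse difference moment
`1/(1+(i−j)²)` under the same name, which is why the cross-check tests
compare matrices and contrast against scikit-image but evaluate
homogeneity with our weights.

**Spectral profiles.** The ROI's "maximum (minimum) reflectance" curve is
the full spectrum of the single brightest (darkest) pixel by total
reflectance, ties broken by row-major first occurrence — not the per-band
pointwise extremum. The two conventions coincide when pixel spectra are
scalar multiples of a shared shape, which holds exactly in the synthetic
model; the pointwise variant is available behind a flag. Band selection is
nearest-neighbour on the wavelength grid with ties to the lower index; the
654 nm analysis wavelength is a configuration default (the melanin
absorption band the study design fixes empirically), not a constant.

**Cohort statistics.** Per metric (brightness, contrast, homogeneity,
mean reflectance at the analysis band, max−min range there): mean, sample
SD (n−1), medians/quartiles with the linear-interpolation quantile
convention (the spreadsheet default, stated because quartiles are
test-visible), paired after−before differences, direction counts
("increase" = strictly positive difference; ties reported separately), a
Shapiro–Wilk normality p per phase, and a two-sided Wilcoxon signed-rank
test. The Wilcoxon implementation drops zero differences, uses average
ranks on ties, takes W = min(W⁺, W⁻), and computes the exact two-sided p
for up to 25 nonzero differences by evaluating the generating function
∏(1 + x^{2rₖ}) of the null distribution of 2·W⁺ (doubling makes tied
average ranks integral, so the enumeration stays exact under ties); beyond
25 a normal approximation with tie correction (variance Σr²/4 from the
realised ranks) and continuity correction is used. Shapiro–Wilk delegates
to scipy with domain checks (3 ≤ n ≤ 5000). No multiple-testing correction
is applied anywhere; the report footer says so.

## Synthetic cohort model

The generator is built backwards from the analysis, so that closed-loop
tests are meaningful.

**Step distributions.** For a texture whose horizontal neighbour
differences e are drawn from a symmetric integer distribution, the
asymmetric right-neighbour GLCM gives exactly contrast = E[e²] and
homogeneity = E[1/(1+|e|)]. A (contrast, homogeneity) target is inverted
on the three-level support {0, ±1, ±m₂}: the two moment equations are a
linear 2×2 system in the magnitude probabilities (p₁, p₂), solved for
candidate m₂ over a small integer grid; m₂ = 8 is tried first (it offers
the widest headroom for skin-like target pairs and is the documented
solution for the flagship pair (5.86, 0.56) → p₀ ≈ 0.182, p(|e|=1) ≈ 0.738,
p(|e|=8) ≈ 0.080), then 2…16 in order. Infeasibility is a real phenomenon,
not an edge case: pushing homogeneity down requires many large steps,
which drive contrast up, so low homogeneity is only attainable jointly
with high contrast. The cohort designer therefore pairs its
lowest-homogeneity patients with its highest-contrast patients — which is
also the empirically expected negative coupling of the two statistics.

**Texture layout.** The rounded step multiset (counts over
rows·(cols−1) slots) is laid out row by row with +e and −e emitted
adjacently, so partial sums stay in a narrow corridor above the row base
level; leftover odd steps become single excursions. Unit order and the
choice of which rows sit one level higher are shuffled by the seed; the
fractional part of the brightness target is realised by raising ⌊frac·R⌉
of the R rows one level. Consequences: measured brightness is within
1/(2R) of target (±0.008 for 64 rows), and measured contrast/homogeneity
equal the realised multiset's moments *exactly*, which are within the
rounding resolution ≈ m₂²/(2N) of the requested targets (≈0.008 contrast
at 64×64). The synthesis degrades gracefully but visibly below ~24×24,
where the multiset rounding quantum becomes material.

**Spectral lifting.** Every pixel receives one shared smooth skin-like
spectral shape s(λ) (low in the blue-green where melanin and haemoglobin
absorb, rising through the red; a logistic ramp centred at 580 nm), scaled
multiplicatively by `scale_cu·g/(G−1)`. This is a deliberately minimal
melanin-like model: darker pixels reflect uniformly less, band-mean
reflectance reproduces the gray level exactly (so gray→cube→gray is exact
up to disk quantisation), and s is adjusted by a Gaussian bump at the
analysis band (two linear constraints: unit band-mean, prescribed value at
the band) so the ROI-mean reflectance at 654 nm hits its target.
Optional seeded Gaussian noise (default SD 0 c.u., so closed-loop
tolerances stay tight) models sensor noise; a robustness test runs at
SD = 2 c.u. and verifies direction counts are unchanged. Cubes are written
to disk as 16-bit raw counts under a spectrally flat lamp at 16×1023
counts, keeping disk quantisation of reflectance below 1/32 c.u.

What this generator does **not** emulate: blotchy spatially correlated
hyperpigmentation spots, pixelwise-independent spectral variation,
haemoglobin features, acquisition artifacts (micromovement, integration
time), or any physical radiative transport. Passing closed-loop tests
therefore demonstrates that the *measurement chain* is correct and
self-consistent, not that it is robust to every property of real skin
images.

**The packaged 12-patient preset.** The study the package follows prints
only cohort-level statistics; per-patient values are free design
parameters. The preset's targets are constructed deterministically to
satisfy all printed statistics simultaneously: per metric, a designed
after−before difference vector fixes the direction counts, the median
shift and the mean shift; the before-phase values are an affine
combination of the standardised difference pattern and a seeded residual
pattern, with the mixing weight forced by
var(after) = var(before) + var(d) + 2cov(before, d), so both phases' means
and SDs are exact. A short deterministic search over residual patterns
rejects candidates violating physical ranges or per-patient (contrast,
homogeneity) feasibility. The resulting table is frozen in
`data/paper_cohort.csv`; `design_paper_preset()` reconstructs it from
scratch and a test asserts the two agree. Any table satisfying the printed
summaries would be equally valid; this one is a documented solution, not a
reconstruction of a real cohort. Default cube shape is 64×64×204 (desk
scale — per-patient statistical resolution comfortably exceeds every
tolerance at this size); the full 512×512 frame size is a preset field.

## Numerical conventions and degenerate inputs

- GLCM matrices are validated to sum to 1 within 1e−9.
- Images with no valid (pixel, neighbour) pair at the requested offset are
  degenerate-input errors; all-zero difference vectors are
  degenerate-data errors for the Wilcoxon test, but a cohort run reports
  them as missing p-values with a warning instead of aborting.
- Calibration requires white > dark in every band after spatial averaging.
- ENVI wavelengths are written with full `repr` precision so round trips
  are bit-exact; BIL/BIP/BSQ interleaves are all supported and read back
  identically.
- Single-patient runs produce per-patient outputs and a warning, no
  cohort statistics.

## Known limitations

- The three-level step family cannot reach every (contrast, homogeneity)
  pair (see feasibility above); the solver raises rather than
  approximating.
- The max/min profile convention assumes the brightest pixel by total is
  brightest at the analysis band; for spectra that cross, the max−min
  range at a single band could be negative under this convention, which
  the band-metrics type rejects loudly rather than silently clipping.
- The exact Wilcoxon enumeration is limited to 25 nonzero differences;
  beyond that the tie-corrected normal approximation is used.
- The CLI's `report` subcommand re-renders from the 6-decimal per-patient
  table, so re-rendered summaries agree with the original run to that
  precision only.
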