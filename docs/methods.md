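# Methods

## Data model

An EEM is a matrix of fluorescence intensities (arbitrary units) indexed
`[emission, excitation]` on strictly increasing wavelength grids (nm), with
an optional boolean mask for excised cells. A study stacks preprocessed
EEMs into a three-way tensor `X[i, j, k]` (sample × emission × excitation).
Dilution is tracked as the dilution factor DF = c/c₀ = V₀/(V₀+V_solvent);
"1:N" labels are read as initial-to-total volume, DF = 1/N (this convention
reproduces every conventional printed value exactly, e.g. 1:200 → 0.005 and
1:6400 → 1.5625e-4, where an initial-to-solvent reading would give
1/201 ≈ 4.975e-3). EEM files are plain delimited matrices (cell [0,0]
empty, header row = excitation nm, first column = emission nm; masked cells
serialize as empty fields and round-trip bit-exactly).

## Preprocessing

Order: blank subtraction → anti-Stokes zeroing → scatter excision →
emission-axis interpolation.

* **Blank subtraction** is cell-wise against the solvent blank. Negatives
  are kept by default (`clip_negative=False`); the downstream
  non-negativity constraints absorb them, and clipping would bias weak
  signals upward. Blank subtraction alone cannot remove scatter: in real
  bile part of the ridge is particulate (Mie) scattering absent from the
  solvent blank, which is why excision follows.
* **Scatter lines.** Rayleigh: λem = λex and 2λex. Raman: constant
  wavenumber shift ν below excitation, λ = 10⁷/(10⁷/λex − ν), doubled for
  second order. Default ν = 3382 cm⁻¹, the water O–H stretch convention of
  the standard EEM scatter-removal tools; it is configurable because the
  1:1 EtOH–H₂O solvent's effective shift is not sharply defined.
* **Excision bands** (nm below/above the line): Rayleigh 1: −10/+20 (30 nm
  total); Rayleigh 2: −15/+20 (35 nm); Raman 1: −15/+5 (20 nm); Raman 2:
  −15/+10 (25 nm). Bands falling outside the emission grid mask nothing;
  masking is idempotent. Note that neighbouring bands can merge into one
  contiguous masked run (e.g. Raman 1 touches Rayleigh 1 for excitation
  near 300 nm), so per-band widths are only measurable with a single band
  enabled.
* **Interpolation** is 1-D along emission within each excitation column
  (linear by default, PCHIP selectable), matching the behaviour of the
  standard tools; leading/trailing masked runs take the nearest unmasked
  value, and a column left with fewer than two unmasked cells is zero-filled
  and flagged. Unmasked cells are never altered. For a surface that is
  affine along emission inside a gap the restoration is exact; otherwise the
  error is the classical chord-interpolation error (for a quadratic, up to
  a·L²/4 at the middle of a gap of width L).
* **Anti-Stokes zeroing** (default on): cells with λem < λex − 10 nm are
  physically meaningless and set to 0. It runs *before* interpolation so
  the lower flanks of the Rayleigh gap are consistent with the final
  surface.
* `residual_scatter_level` re-interpolates across the band footprint and
  reports the maximum deviation of the stored values from it — a quality
  metric whose target is < 2 AU on processed data (trivially ~0 right after
  the pipeline's own interpolation; meaningful on externally preprocessed
  input).

## Inner-filter screening

Dilution curves sample one (excitation, emission) cell — nearest grid cell,
no interpolation — across a source's dilution series, defaulting to the
argmax cell of the most dilute EEM. The IFE flag requires both an intensity
maximum away from the highest concentration and a drop at the largest DF
below (1 − drop_tol)·max, with drop_tol = 0.05: a turnover, not mere
flattening within noise. The reported linear range is the largest DF up to
which intensity/DF stays within drop_tol of its most-dilute value. For the
family F ∝ DF·10^(−β·DF) the curve peaks at DF* = 1/(β ln 10), which the
detector recovers as the grid is refined.

Thin-limit selection keeps DF ≤ 0.0025 (the 1:400 dilution) by default,
with explicit per-sample overrides, and writes a per-record
included/excluded report with reasons.

## PARAFAC

`X[i,j,k] = Σ_f A[i,f]·B[j,f]·C[k,f] + E[i,j,k]`, fitted by alternating
least squares with exact non-negative least-squares sub-solves per mode.
Within a mode update every row shares the same F×F Gram matrix (the
Hadamard product of the other modes' Grams), so the NNLS solutions are
found by enumerating candidate active sets and checking KKT conditions,
batched over rows — exact and far faster than per-row solver calls for the
small F (≤ 7) used here; a row-wise Cholesky NNLS is the numerical
fallback. RSS is computed each iteration from the just-solved normal
equations and is non-increasing within a start (asserted in tests).

* Convergence: relative RSS change < 1e-6, at most 2500 iterations.
* Multi-start: 10 random non-negative initializations (SVD-based
  initialization selectable), seeds spawned from the master seed; the
  lowest-RSS solution is kept.
* Scaling: B and C columns normalized to unit maximum, magnitude absorbed
  into A, so scores are comparable across samples; the reconstruction is
  invariant to the convention. Factors are ordered by descending total
  score, ties by ascending excitation peak.
* The blank is subtracted upstream and never added as a pseudo-sample —
  doing so adds spurious degrees of freedom and creates an artifact factor.

**Core consistency (CORCONDIA).** The least-squares Tucker core G given
the fitted loadings is computed via mode-wise pseudo-inverses (the
pseudo-inverse of a Kronecker product is the Kronecker product of
pseudo-inverses) and compared with the superidentity T:
`100·(1 − Σ(g−t)²/F)`, unclipped (can be negative). Exact-rank noiseless
fits give 100; any converged one-factor model gives exactly 100 (its 1×1
LS core is 1 at an ALS stationary point); over-factored models collapse.
Rank-deficient loadings raise a degenerate-model error.

`model_sweep` tabulates (F, core consistency, RSS, convergence) across a
factor range; RSS should be non-increasing in F, and violations are
surfaced as local-optimum warnings rather than errors. Factor matching
between models maximizes summed Tucker congruence (cosine) of concatenated
(B, C) profiles via linear assignment.

## Diagnostics

* **Discrepancy maps.** Residuals R = modeled − observed are pooled over
  samples; for each wavelength cell the window collects all cells within
  ±10% *of that cell's wavelength* on both axes (a wavelength-proportional
  window — the natural reading of "±10%" for a quantity in nm; a 0 fraction
  degenerates to per-cell statistics). Windows truncate at grid edges.
  Bias = mean(R), RMSE = √mean(R²), and SD is derived as
  √(RMSE² − bias²) with population (n) normalization, so
  RMSE² = bias² + SD² holds exactly by construction. Implementation uses
  2-D prefix sums, O(JK) overall.
* **RMA regression** of modeled on observed: slope = sign(r)·sd(y)/sd(x),
  intercept from the means, r² the squared Pearson correlation (RMA has no
  unique r²; this matches common usage). Both surfaces carry error, which
  is why ordinary least squares (slope biased toward 0) is not used.
  Symmetry: slope(y|x)·slope(x|y) = 1.
* **Per-sample fit:** per-sample RMSE, mean |fluorescence| and their ratio
  (NaN for a zero-mean sample); weakly fluorescent samples show larger
  ratios because the residual floor is shared while the signal is not.
* **Score–DF curves** per (factor, source), with a monotonicity flag
  (tolerance 1e-9 of the curve maximum) and the first offending DF pair.
* **Equal-score concentration ratios.** For each source the DF reaching a
  chosen score level is interpolated log-log along its curve (dilution
  ladders are geometric, so log-log segments are near-linear);
  ratio = DF*(reference)/DF*(source). Curves must bracket the level.
  Score inversions smaller than 5% of the curve maximum — the kind left at
  the noise floor of the deepest dilutions — are absorbed by interpolating
  on the isotonic envelope; larger inversions are an error. Rescaling all
  curves by a common factor leaves ratios of power-law curves unchanged.

## Synthetic study generator

The generator emulates the study design, not bile photophysics: excitation
190–400 nm and emission 250–600 nm at 5 nm (43 × 71 points; an
`extend_emission` flag continues to 650 nm / 81 points, covering the two
grid sizes in circulation for this design), 7 sources (three lab
pools and a reference-river and polluted-river pool of the
inner-filter-prone species, two individuals of the second species), serial
dilutions 1:100…1:6400 (factor 2, 7 levels).

Per sample: the clean trilinear part
`L[j,k] = Σ_f conc_f·DF·quantum_f·b_f[j]·c_f[k]` with unit-max Gaussian
loadings; inner-filter attenuation `10^(−(A_ex+A_em)/2)` with absorbance
`A = Σ_f conc_f·DF·absorptivity_f·(loading)` (the standard primary +
secondary absorption model); a flat blank background (5 AU) plus
Gaussian-cross-section scatter ridges on all four lines (sd 2 nm, solvent
fraction 0.6 of ridge height so blank subtraction leaves a residual ridge,
as with Mie scatter in real bile); i.i.d. Gaussian noise with
sd = 1% of the study's maximum clean signal. Every draw is governed by the
scenario seed, and each EEM carries its truth record (clean surface, true
scores, loadings).

Default fluorophores: tryptophan-like (Ex 225/Em 360, FWHM 40/55 nm), a
second component (Ex 270/Em 450, 45/60 nm) and the second-species-dominant
component (Ex 345/Em 410, 45/50 nm). FWHMs are plausible for protein-like
and humic-like bile fluorophores but not measured quantities. Factor-1
concentrations are planted at POLLUT : REF : LAB : PIO = 16 : 3 : 1 : 0.09
and factor 2 at 21 : 4 : 1 : 0.25; factor 3 is ~6× more abundant in the
second species. Absorptivities (15/10/2 per unit concentration) make
fluorophores 1–2 the strong absorbers. With absorbance tied to fluorophore
concentration (as specified by the forward model) and a 16-fold
concentration spread, the dilution-curve maxima cannot fall at the same
dilution for every source; the values are chosen so the brightest source
peaks in the 1:400–1:800 window, the mid source just inside the measured
ladder, while the lab source shows only curvature — real bile, whose
absorbance is matrix-dominated, would place all maxima together.

What passing tests on this generator do **not** show: robustness to
wavelength-dependent instrument response, drift, pH/quenching chemistry,
Mie-scatter spectral shape, or non-Gaussian component profiles. In
particular, recovery of a factor that is ~100× weaker than a co-occurring
one in the same sample (the second species' tryptophan trace) is degraded
by the preprocessing interpolation at the few-tens-of-percent level, which
is why the equal-score ratio check for that source is performed on
artifact-free surfaces.

## Pipeline and reproducibility

`run_pipeline` executes load → preprocess → thin-limit select → sweep →
report. The reported factor count defaults to the best core consistency
among F ≥ 2 (override with `report_factors`). The report bundle
(preprocessed EEMs, exclusion report, sweep table, loadings/scores CSVs,
discrepancy maps, monotonicity report, summary JSON, run log) is
self-describing: every number is recomputable from the archived inputs and
the logged options. A single master seed fans out to per-stage seeds by
FNV-1a hashing (< 2³¹); deterministic stages are bit-reproducible across
reruns. An aborted run names the failing stage and sample and never writes
the `COMPLETE` marker. `subset_runs` repeats the sweep on named sample
subsets and matches factors across subsets to assess their persistence as
the dataset grows in heterogeneity.

Problem sizes in the test suite and acceptance script (7 × 7-sample study,
35-sample thin-limit tensor of 71 × 43 cells, 10 starts, 10 seeds) keep a
full run in seconds on one CPU while leaving every planted contrast
resolvable.

## Known limitations

* Missing-data ALS is out of scope; gaps must be interpolated upstream.
* The CORCONDIA denominator is the superidentity norm (= F); other
  implementations sometimes normalize by the core norm, which differs for
  badly misspecified models.
* Absorbance-based inner-filter *correction* is deliberately not offered —
  the design choice is exclusion, matching the thin-limit modeling
  assumption.
* RMA r² is reported as squared Pearson correlation; it is a descriptive,
  not an inferential, quantity here.
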