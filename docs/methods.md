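# Methods

This note documents the models implemented in `mycospec`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Data model

A spectral block is a samples × wavenumbers matrix on one shared grid,
stored with wavenumbers strictly **descending** (the instrument
convention); all region bounds are closed intervals in cm⁻¹. The default
digital spacing is 1.928 cm⁻¹ on 3785–50 cm⁻¹ (FT-Raman) and 4000–400 cm⁻¹
(FTIR). Grid alignment uses piecewise-linear interpolation restricted to
the common overlap — never extrapolation. The canonical on-disk format is a
wide CSV (row = spectrum) with sidecar metadata/chemistry CSVs keyed by
sample id; values are written with shortest-roundtrip `repr`, so
write→read is bit-lossless. A minimal JCAMP-DX reader (AFFN
`(X++(Y..Y))` tables) covers single-spectrum exports.

The cultivation design is 6 strains (Ar, Mc1, Mc2, Mr, Rs, Uv) × 3
phosphate levels (Pi0.5/Pi1/Pi4) × 2 calcium levels (Ca0/Ca1) × 2
biological replicates = 72 biological samples, each measured in 3 technical
replicates (216 spectra per block).

## Preprocessing

Four recipes, applied strictly in order:

| recipe           | steps |
|------------------|-------|
| `raman_nonderiv` | SG(2, 15, 0) → rubber band → truncate 3200–2400 ∪ 1900–500 → EMSC(3) |
| `raman_deriv`    | SG(2, 15, 2) → EMSC(3) → truncate 1800–900 |
| `ftir_nonderiv`  | EMSC(3) |
| `ftir_deriv`     | SG(2, 15, 2) → EMSC(2) → truncate 1800–900 |

**Savitzky–Golay.** scipy's filter with `mode="interp"` (one-sided
polynomial fit at the edges, no reflection padding). The descending grid is
flipped to ascending before differentiation and flipped back, and
derivatives are scaled by the grid spacing, so order-d output is per
(cm⁻¹)^d.

**Rubber band.** The baseline is the lower convex hull of the
(wavenumber, intensity) points, computed by a monotone-chain walk (robust
to collinear runs), evaluated piecewise-linearly and subtracted. The
corrected spectrum is ≥ 0 everywhere, exactly 0 at the hull vertices and
both endpoints, and the operation is idempotent. Peaks must point upward.

**EMSC.** Per spectrum, least squares of `s ≈ a·m + Σ_{k=0..d} c_k u^k`
with `u` the wavenumber axis rescaled to [−1, 1] and monomial baseline
terms (conditioning is unproblematic at d ≤ 3); corrected = `(s − Σ c_k
u^k)/a`. "Linear, quadratic and cubic components" is read as a degree-3
model *including* the constant (MSC's offset) term. The output is invariant
to multiplicative rescaling of the input. The reference spectrum defaults
to the mean of the set being corrected; during calibration the reference is
the mean of the **training partition only** (computed at the EMSC stage of
the recipe) and is reused unchanged on the validation partition, so no
information leaks across the bioreplicate split. A singular design
(reference collinear with the polynomials) or vanishing `a` raises with
advice to pick a different reference.

**Replicate averaging.** Technical replicates are averaged after
preprocessing (216 → 72 rows), giving the two blocks sample-to-sample
correspondence for CPCA and the ANOVA decomposition.

## Replicate QC

For each biological sample, all pairwise Pearson correlations between its
technical replicates across the wavenumber axis; variability = 1 − mean
pairwise PCC (mean, not min/max — an aggregation choice, recorded here).
Pairs with a zero-variance spectrum are excluded with a warning. The test
is run on preprocessed non-derivative FT-Raman data, and the output is
sorted most-variable-first.

## PCA and consensus PCA

PCA is computed by SVD of the mean-centered matrix; explained variances are
percentages of total variance; the sign convention makes each component's
largest-magnitude loading positive, so results are reproducible to the bit.

CPCA centers each block, scales block b by `w_b = sqrt(mean_b(SS_b)/SS_b)`
(equalizing every block's total sum of squares, normalized so the average
block keeps its magnitude), and runs PCA on the column-concatenated scaled
super-matrix. Block loadings are the global-loading segments renormalized
to unit length; block scores are the scaled block matrices projected on
them; a block's contribution to a component is the squared norm of its
global-loading segment (in %). With these weights the concatenated-PCA
formulation extracts the same components as the NIPALS consensus algorithm,
deterministically. Consequences of the weight normalization: a single-block
CPCA equals plain PCA exactly; two identical blocks contribute 50/50;
multiplying any block by a constant leaves loadings, contributions and
explained variances unchanged and rescales all scores by one common factor.

## PLSR

Single-response PLS fitted by NIPALS (weight → score → loading → deflation)
on mean-centered data, coefficients retained for every component count A.
Cross-validation inside the calibration partition is
leave-one-biological-sample-out (all technical replicates of a sample held
out together). AOpt is the smallest A whose RMSECV ≤ (1 + τ)·min RMSECV
with τ = 0.05 by default; the one-standard-error rule is available
(`tolerance_rule="one_se"`). Validation follows the study design: calibrate
on bioreplicate 1, validate on bioreplicate 2; models are fitted on
replicate-level spectra and predictions are reported per biological sample
as replicate means; responses stay in their reference units (% dry weight;
µg/g dry weight). Reports carry both calibration and validation R²/RMSE,
since printed tables of this kind are often ambiguous about which is shown.
Overlapping sample ids between partitions raise a leakage error (a
degenerate train==test sanity check requires `allow_overlap=True`).

Band ratios read intensities at the nearest grid points (lookup error ≤
half the 1.928 cm⁻¹ spacing) on non-derivative data. Preset pairs:
(1747, 1445) lipids, (1163, 1155) polyphosphates, (1523, 1445) carotenoids.
The polyphosphate numerator is quoted at 1163 cm⁻¹ while the band catalog
centers the P=O stretch at 1165 cm⁻¹; at the instrument spacing both
resolve to the same grid point.

## ANOVA decomposition

Per strain and block, on replicate-averaged derivative data truncated to
1800–900 cm⁻¹ (the derivative recipe is the default; the recipe is a
parameter and is recorded in the output): the grand-mean-centered 12-row
matrix (3 Pi × 2 Ca × 2 bioreplicates, balanced — enforced, because
additivity fails silently otherwise) is decomposed into level-mean effect
matrices for Ca (2 levels), Pi (3), Ca×Pi interaction (cell mean minus both
main effects — the classical two-way definition, which avoids
double-counting the main effects inside the 6-level interaction), and
bioreplicate (2), plus residual. In the balanced design the five matrices
are mutually orthogonal and sums of squares are additive. Contributions are
normalized over the four design factors (summing to 100%); the residual is
reported separately as a share of total SS — both numbers are emitted
because either normalization is defensible.

## Synthetic-data generator

The generator realizes the band catalog as sums of unit-peak Lorentzians
(default FWHM 16 cm⁻¹; 10 cm⁻¹ for the resonance-enhanced carotenoid bands;
broad O-H/N-H envelopes at 120 cm⁻¹ in FTIR). Catalog structure encodes the
blocks' chemistry: carotenoid bands (1525, 1155, 1005 cm⁻¹) exist only in
the Raman catalog and are enhanced ~three orders of magnitude per unit
concentration (resonance effect); polyphosphate bands are weak in Raman
(1165, 685) and strong in FTIR (1263, 885); lipid C-H stretches are the
strongest Raman bands.

Each spectrum is `gain · Σ_c conc_c · pure_c + drift + heating + noise`:

- **Concentrations** (mass fractions, shared between blocks and technical
  replicates of a sample): per-strain lipid and phosphorus levels are
  centered on the midpoints of the published per-strain ranges and pushed
  toward the range ends by the phosphate level (lipids up under low Pi,
  phosphorus up under high Pi, 80% of the half-range); polyphosphate mass
  is 3 g per g phosphorus; chitin is boosted 1.5× under Pi0.5 (acid-stress
  overproduction) and suppressed 0.6× without calcium (calcium-dependent
  chitin synthase); carotenoids in the pigmented strains (Ar, Mc1, Mc2)
  follow condition multipliers with Mc2's 10× surge at (Pi0.5, Ca0).
  Biological jitter is log-normal, s.d. 0.08 (0.35 for carotenoids —
  pigment production is far more variable than bulk composition).
  **Mass closure**: dry-weight fractions live on the simplex, so the
  structural pool (chitin + chitosan/glucan + protein) is rescaled to fill
  exactly the dry weight left by lipids, polyphosphates and carotenoids.
  Closure is what makes EMSC-normalized spectra ~linear in %DW responses
  and induces the lipid-versus-carbohydrate anti-correlation seen in real
  biomass.
- **Gain** is log-normal (s.d. of log 0.15) per spectrum; **drift** is a
  random cubic polynomial (coefficient scale 0.03 Raman / 0.08 FTIR, in
  intensity units); **noise** is white with s.d. 0.005 (≈0.5% of a typical
  band).
- **Heating**: ten biological samples — Rhizopus stolonifer at Pi1/Pi4 and
  two Amylomyces rouxii cells — are flagged as heating-affected
  (dark-spore absorption of the laser), marked as measured at 200 mW
  instead of 500 mW, and receive a broad Gaussian emission baseline
  (amplitude 0.6 scaled by 0.4 for the reduced power, center −600 cm⁻¹ —
  off-grid, so only its low-wavenumber rise is seen — σ 900 cm⁻¹, jittered
  per replicate) plus 4× white noise, which reproduces their degraded
  replicate reproducibility. The heating magnitude is a free parameter of
  the simulator, not a measured quantity.

One seed drives five independent substreams (concentrations, gains,
drifts, noise, heating), so each source can be zeroed in tests without
perturbing the others; output is bit-reproducible per seed.

What the generator does **not** emulate: physically accurate Raman cross
sections, fluorescence and photobleaching kinetics, instrument line-shape
and apodization effects, atmospheric water/CO₂ interference, detector
nonlinearity, and reference-analysis measurement error (the chemistry table
is exact truth). Passing recovery tests therefore demonstrates the
correctness and statistical behavior of the workflow under the assumed
signal model — not instrument-level performance on real biomass.

## Numerical choices and degenerate inputs

- EMSC solves one shared least-squares design per set via `lstsq`; rank
  deficiency and vanishing multiplicative coefficients raise informative
  errors.
- The hull walk pops collinear points, so straight-line and convex spectra
  correct to exactly zero.
- PLS extraction stops early when residual variance is exhausted
  (`n_components` may be smaller than requested); zero-variance responses
  are rejected.
- PCA/CPCA sign ties (largest-|loading| exactly zero) default to +1.
- Balanced-design checks, replicate-group metadata consistency, empty
  truncations, empty grid overlaps, and partition leakage all raise typed
  errors rather than propagating silent wrong answers.
- Problem sizes: the default study is 216 spectra × ~1900 points per block;
  the null-distribution check of the ANOVA decomposition uses 200
  repetitions of a 12 × 40 matrix; the QC ranking check uses 100 trials of
  12 samples × 3 replicates × 300 points.

## Known limitations

- CPCA is implemented for the chosen equal-SS block weighting only; other
  weightings (e.g. per-variable scaling) and hierarchical multiblock
  variants are out of scope.
- The ANOVA module reports contributions only; ANOVA-PCA/ASCA score plots
  and permutation tests are deliberately not implemented.
- PLS2 (multi-response), variable selection, and outlier removal policies
  are out of scope; QC reports ranking but never drops samples.
- JCAMP-DX support covers AFFN tables only (no compressed DIF/DUP forms).
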