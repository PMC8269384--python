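# mycospec

Chemometric assessment of filamentous fungal biomass from FT-Raman and
FTIR spectra.

Oleaginous Mucoromycota fungi (e.g. *Umbelopsis vinacea*, *Mucor
circinelloides*) accumulate lipids, cell-wall polysaccharides (chitin,
chitosan, glucans), polyphosphates and carotenoid pigments, making them
attractive cell factories. Vibrational spectroscopy can read this chemistry
directly from intact biomass: FTIR through polar-bond absorption, FT-Raman
(1064 nm excitation) through scattering by non-polar bonds — and, thanks to
the resonance Raman effect, Raman sees trace carotenoids that FTIR cannot.
`mycospec` implements the complete analysis workflow for such screening
experiments, for spectroscopists and bioprocess researchers who want a
tested, scriptable alternative to point-and-click chemometrics tools:

- **Preprocessing** — Savitzky–Golay smoothing/differentiation,
  rubber-band (lower convex hull) baseline correction, region truncation,
  and extended multiplicative signal correction (EMSC): each spectrum `s`
  is fitted as `s ≈ a·m + Σₖ cₖ uᵏ` against a reference `m` with a
  polynomial baseline in the rescaled wavenumber `u ∈ [−1, 1]`, and
  corrected to `(s − Σₖ cₖ uᵏ)/a`.
- **Replicate QC** — the 1−PCC variability score: one minus the mean
  pairwise Pearson correlation between technical-replicate spectra.
- **Factor models** — PCA and consensus PCA (CPCA) of multiple row-aligned
  spectral blocks, with global scores, per-block scores/loadings and block
  contribution percentages.
- **Calibration** — single-response PLSR (NIPALS) with leave-one-
  biological-sample-out cross-validation, parsimonious component selection
  (smallest A with RMSECV within 5% of the minimum, or the one-SE rule),
  and strict bioreplicate-held-out validation; plus band-intensity ratios
  I(1747)/I(1445) (lipids), I(1163)/I(1155) (polyphosphates) and
  I(1523)/I(1445) (carotenoids).
- **Design ANOVA** — decomposition of each strain's spectral matrix into
  calcium, phosphate, Ca×Pi-interaction and bioreplicate effect matrices
  plus residual, with factor contributions as shares of sums of squares
  (the decomposition underlying ANOVA-PCA/ASCA).
- **Synthetic data** — a generator that emulates the full cultivation
  design (6 strains × 3 phosphate levels × 2 calcium levels × 2 biological
  × 3 technical replicates = 216 spectra per block) with Lorentzian band
  profiles per biochemical component, design-driven concentrations with
  mass closure, multiplicative scatter, polynomial drift, laser-heating
  baselines and noise — with the true chemistry returned as ground truth.

## Worked example

```python
from mycospec import (
    synth_dataset, make_recipe, fit_apply_recipe, validate_bioreplicate,
)

raman, ftir, chemistry = synth_dataset(seed=1)        # 216 spectra per block

mc = raman.select_strains(["Mc1", "Mc2"])             # the two pigmented strains
train = mc.select((mc.meta.bio_rep == 1).to_numpy())  # calibrate on bioreplicate 1
test = mc.select((mc.meta.bio_rep == 2).to_numpy())   # validate on bioreplicate 2
report = validate_bioreplicate(
    train, test, response="carotenoid_ug_per_g",
    max_components=10, recipe=make_recipe("raman_nonderiv"),
)
print(f"AOpt={report['aopt']}  R2(val)={report['r2_val']:.3f}  "
      f"RMSE(val)={report['rmse_val']:.1f} ug/g")
```

prints

```
AOpt=3  R2(val)=0.994  RMSE(val)=103.7 ug/g
```

i.e. three latent components suffice to predict total carotenoids of
held-out biological replicates to about 104 µg/g dry weight over a range
spanning tens to ~1700 µg/g — possible only in the Raman block, where the
resonance-enhanced carotenoid bands at 1525, 1155 and 1005 cm⁻¹ live; the
same model on the FTIR block collapses to R² ≈ 0.07.

The same dataset run through the whole pipeline:

```bash
python -c "
from mycospec import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=1, out_dir='run1'))"
```

writes preprocessed matrices, the QC variability table, PCA/CPCA scores and
loadings, PLSR reports, band-ratio tables, the 6-strain × 2-block ANOVA
contribution table and a machine-readable `summary.json` (byte-identical on
rerun at the same seed). The CLI mirrors every stage:
`mycospec simulate|preprocess|qc|pca|cpca|plsr|ratio|anova|run`.

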