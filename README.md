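# melaband

Spatial and morphological prognostication for melanoma from multiplex
immunohistochemistry (mIHC). Cutaneous melanoma is staged largely on
Breslow thickness and mitotic rate, yet outcomes vary widely within
those strata. This package implements a computational pipeline that asks
whether *where* cells sit in the tumor and *how large their nuclei are*
add prognostic signal: it phenotypes cells from per-cell detection
tables (DAPI / Ki67 / S100 mean intensities), splits each tumor into
depth bands, extracts per-band morphometric factors, and evaluates them
in Cox proportional-hazards models. It is written for computational
pathology researchers who have per-cell exports from detection software
(e.g. QuPath/StarDist) plus polygon annotations, and for methodologists
who want a fully simulated test bed for this class of analysis.

## The pipeline

1. **Marker gating** (`melaband.gating`). Per slide and marker, a
   two-phase adaptive threshold on the log of one compartment's mean
   intensity: an Otsu split maximizing the between-class variance
   σ²_B(t) = ω₀(t)·ω₁(t)·[μ₀(t) − μ₁(t)]² separates the background
   component T0 from the foreground T1; a 2-component Gaussian mixture
   p(x) = π₁N(x|μ₁,σ₁) + π₂N(x|μ₂,σ₂) fitted to ln T1 by EM (weak
   conjugate priors, max 3000 iterations) places the final threshold at
   the weighted-density intersection π₁N(x|μ₁,σ₁) = π₂N(x|μ₂,σ₂), the
   higher-mean component being the positive population. A bimodality
   guard (Ashman's D ≥ 2, min weight ≥ 0.10) keeps the intersection from
   bisecting a single population when T1 carries no second mode.
2. **Band geometry** (`melaband.geometry`). PCA of the tumor boundary
   gives the depth axis and the estimated thickness T (the longest
   epidermis-to-deepest-point span); a distance transform from the
   superficial boundary assigns each raster pixel a depth; cutting at
   T/3 and 2T/3 yields the Superficial, Middle and Invasive bands, and
   the boundary opposite the epidermis at depth ≥ 2T/3 is the invasive
   margin.
3. **Feature table** (`melaband.features`). Per band and overall: cell
   and colocalized-cell densities (cells/mm²), colocalized-to-total and
   colocalized-to-tumor ratios (tumor = S100+, colocalized = S100+Ki67+),
   and mean nucleus areas (µm²) per category — joined with age, mitoses
   per HPF, Breslow thickness and the estimated thickness (mm).
4. **Survival statistics** (`melaband.survival`). Univariable and
   multivariable Cox models fitted by Newton–Raphson on the Breslow
   partial likelihood, with HR = exp(β), 95% Wald CIs and p-values;
   Harrell's concordance with percentile-bootstrap CIs; leave-one-out
   cross-validated concordance on pooled out-of-fold linear predictors.
5. **Reporting** (`melaband.reporting`). Factor correlation matrices
   with significance stars, publication-style figures, and a
   `run_pipeline` driver composing the whole chain.

Because no real per-cell melanoma cohort is bundled, everything runs on
`melaband.synthetic`: slide simulations with two-component log-normal
marker mixtures and latent truth sidecars, and Weibull
proportional-hazards cohorts — including a full "study" in which a
latent per-patient morphology score shifts invasive-band nucleus areas
*and* drives the hazard, so the pipeline's ability to recover a real
spatial-morphology effect can be measured.

## Worked example

The `analysis/` scripts run the bundled 40-patient demo study
(`analysis/demo_config.yaml`: a planted effect of 0.8 log-hazard per
standard deviation of the latent invasive-band nucleus-size score):

```sh
python analysis/01_simulate_study.py
python analysis/02_gate_markers.py
python analysis/03_segment_bands.py
python analysis/04_assemble_features.py
python analysis/05_fit_survival_models.py
python analysis/06_correlate_factors.py
```

which prints, step by step:

```
wrote 40 slides (50513 cells) to .../scratch/demo/study; 28/40 patients with an event
gated 40 slides; mean accuracy vs latent truth 0.958; 0 failed gates
banded 40 slides; median estimated thickness 1.98 mm
assembled 40 patients x 47 columns; invasive-band mean nuclei size 39.5 ± 5.1 µm²
univariable screen over 24 factors (28/40 events); planted factor
  invasive_mean_nuclei_size: HR 1.153 (1.045, 1.272), p 0.0044, C 0.72
base model (mitosis + thickness): C 0.60 (0.51, 0.72), LOOCV C 0.55 (0.40, 0.69)
correlation matrix over 14 factors; invasive nuclei size vs thickness: r = -0.14 (ns)
```

Reading the output: marker gating reproduces the simulation's latent
positivity labels for ~96% of cells without any manual thresholds; band
segmentation recovers the simulated tumor depths; and the univariable
Cox screen flags the planted factor — each extra µm² of mean
invasive-band nucleus area multiplies the hazard by 1.15 (95% CI 1.05,
1.27), with a concordance of 0.72 — while the traditional-factor base
model, which carries no planted signal here, sits near chance. Summary
tables and figures land in `results/demo/`, bulky per-slide
intermediates in `scratch/demo/`. The same chain is available as one
call (`melaband.reporting.run_pipeline`) or via the `melaband` CLI
(`simulate`, `gate`, `bands`, `survival`, `report`, `pipeline`).

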