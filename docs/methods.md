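# Methods

This note records the models, the defaults and the judgement calls
behind `melaband`, in the package's own words.

## Input model and conventions

The pipeline consumes (a) per-cell detection tables — one row per
detected cell with centroid (µm), nucleus area (µm²) and the mean
intensity of each channel (DAPI, Ki67, S100) in each compartment
(nucleus, cytoplasm, membrane); (b) GeoJSON slide annotations with one
`tumor` and one `epidermis` polygon in µm; (c) a clinical table (age,
mitoses/HPF, Breslow thickness in mm, survival time in months, event
flag, optional endpoint label and sex). Coordinates follow the image
convention (y grows downward), so depth increases with y on a
superficial-at-top slide; nothing downstream depends on that choice
because the depth axis is estimated per slide. Breslow thickness stays
in mm and geometry in µm; the ÷1000 conversion happens once, at feature
assembly. Upstream detection settings (detection probability cutoff,
scan pixel size, percentile normalization) are treated as provenance
metadata: the pipeline starts from the detection table, not the image.

Only the *mean* intensity of one configured compartment per marker is
used for gating. Which compartment best represents a marker is
genuinely data-dependent; the default map (Ki67 → nucleus mean, S100 →
cytoplasm mean) matches each marker's localization and is configurable.

## Two-phase marker gating

Per slide and marker the gate is fitted on log intensities. Expression
values of fluorescence markers are log-normal-like; the histogram is
bimodal on the log scale, and both phases therefore operate there
(cells with non-positive intensity are counted, logged and treated as
background). The final threshold is reported on the linear scale as the
exponential of the log-space value. The whole chain is equivariant
under multiplying all intensities by a constant.

**Phase 1 — Otsu split.** `otsu_threshold` scans all boundaries of a
256-bin histogram spanning the 1st–99th percentile of the values
(outliers clamp into the end bins, so a single extreme value cannot
stretch the binning) and maximizes the between-class variance
σ²_B = ω₀ω₁(μ₀−μ₁)². Class means come from per-bin value sums rather
than bin centers, so the scan is *exactly* the brute-force maximizer
over bin boundaries — the test suite checks this against an independent
enumeration oracle. Ties (flat plateaus, e.g. two well-separated point
masses) are resolved by reporting the midpoint of the first and last
maximizing boundaries. Values at or below the threshold form T0
(background/noise); only T1 proceeds.

**Phase 2 — mixture intersection.** A 2-component Gaussian mixture is
fitted to ln T1 by MAP-EM with weak conjugate priors: symmetric
Dirichlet (concentration 1) on the weights, and normal–inverse-gamma
priors centered on the data (κ₀ = 10⁻³, a₀ = 10⁻³, b₀ = a₀·var) that
bound the variances away from zero without moving a well-identified
fit. Initialization is a deterministic median split of ln T1 — no
random restarts, so a slide gates identically on every run. The
penalized objective is non-decreasing by construction (asserted in
tests); convergence is a change below 10⁻⁶, with a cap of 3000 sweeps
(fits that hit the cap are flagged but usable). The threshold solves
π₁N(x|μ₁,σ₁) = π₂N(x|μ₂,σ₂): a linear equation when σ₁ = σ₂, otherwise
a quadratic whose root in (μ₁, μ₂) is taken; if no root lies between
the means (possible under extreme weight imbalance) the point of
closest approach of the two weighted log-densities is used and flagged
`fallback_used`.

**Bimodality guard.** The intersection only refines the Otsu boundary
when the fitted pair describes two real modes: Ashman's
D = √2·(μ₂−μ₁)/√(σ₁²+σ₂²) ≥ 2 and lighter weight ≥ 0.10. The guard
exists because the maximum-likelihood 2-component fit to a
*single*-population T1 (which arises whenever phase 1 already cut in
the expression valley) places both components inside that population
and the intersection would then split it in half; with the guard the
gate keeps the phase-1 boundary instead. On slides whose T1 genuinely
contains background and expressing populations the guard passes and
the intersection is used. Both constants are standard clean-separation
conventions and were fixed a priori. Known limitation: a slide with
*no* expressing cells gates its upper background tail positive unless
the mixture degenerates entirely (coincident means fail the gate and
mark all cells negative); marker-absent slides should be QC'd out
upstream.

A cell is positive iff its value lies in T1 and its log value is at or
above the final threshold.

## Band geometry

The depth axis is the principal axis of the (densified) tumor boundary
most aligned with the epidermis-centroid → tumor-centroid direction,
oriented away from the epidermis. Estimated thickness T is the spread
of boundary projections along that axis; it is exact on rectangles and
rotation-invariant to raster tolerance. The superficial boundary is the
part of the tumor outline within 50 µm of the epidermis polygon
(fallback: the lowest depth-projection decile, logged). Depth is the
Euclidean distance to that polyline — a distance transform evaluated
exactly at raster pixel centers (10 µm default) for band areas and
polygons, and at cell centroids for per-cell annotation, so cells and
areas share one depth definition. Cutting depth at T/3 and 2T/3
(half-open, lower-inclusive; beyond-T depths are invasive) partitions
the tumor; band areas are pixel counts × pixel area and sum to the
rasterized tumor area exactly. The invasive margin is the boundary
subset at depth ≥ 2T/3 whose outward normal points away from the
epidermis (cosine with the depth axis > 0.3) — the normal condition
excludes the tumor's lateral walls, so a rectangle's margin is exactly
its deep edge. Choices that were genuinely open: whether depth is
measured from the epidermis side or the margin side (epidermis side
chosen, consistent with "superficial/middle/invasive" naming), and
whether PCA runs on boundary points or cell centroids (boundary, so the
geometry does not depend on cellularity). Multi-fragment tumors are out
of scope (the largest fragment governs the bounds).

## Feature table

Categories: total (any cell in the tumor), tumor (S100+), colocalized
(S100+ ∧ Ki67+). Per band — superficial, middle, invasive, plus
"overall" (whole tumor; area = sum of band areas) — the factors are
density (count / band area in mm²), colocalized density, the two
colocalization ratios, and the mean nucleus area per category.
"Nucleus size" means area in µm²; hazard ratios for size factors are
therefore per µm². An empty category × band yields a *missing* mean
size (never zero); a ratio is 0 when only its numerator is empty and
missing when its denominator is. Patients in the clinical table without
a slide are excluded with a log entry. Missing factor values are
handled complete-case per model downstream, with per-model n reported.

## Survival statistics

`cox_fit` maximizes the Breslow partial likelihood by Newton–Raphson
with analytic gradient and observed information (Efron's correction is
available behind `ties="efron"`, delegated to lifelines). Breslow is
the default because it is the simplest exactly-documentable tie rule
and is what the grid-search oracle maximizes. Covariates are centered
and scaled internally for conditioning and transformed back. Newton
steps are halved until the likelihood does not decrease; convergence is
max|score| < 10⁻⁸ or step < 10⁻¹⁰ within 100 iterations. A fit whose
per-sd coefficient exceeds 10 is flagged as monotone likelihood
(perfect separation) rather than raised. SEs come from the inverse
observed information; CIs and p-values are two-sided Wald.

Harrell's C counts pairs where the strictly earlier time has an event;
ties in score count ½; zero comparable pairs is an error. The apparent
C's CI is a percentile bootstrap (default B = 1000) over patient
resamples with a full refit per replicate; replicates with < 2 events
are skipped (warned above 10%). LOOCV concordance pools each patient's
out-of-fold linear predictor and computes one C on the pooled vector;
its CI bootstraps the pooled (predictor, time, event) triples. Pooling
is one defensible definition among several; it is deterministic and
uses every patient exactly once as a validation case. The univariable
screen fits one model per factor with no multiple-testing correction
(noted in output metadata); the multivariable family is the
traditional base (mitosis + Breslow thickness) plus one invasive-band
nuclei-size factor at a time, with near-perfect collinearity (|r| >
0.999) rejected. Correlation analysis defaults to Pearson (Spearman
behind a flag), pairwise complete-case, p from the t-transform of r,
stars at p < 0.05/0.01/0.001, unadjusted.

## Synthetic data: what it emulates and what it does not

`generate_slide` emulates a detection-table export: uniform Poisson
cell scatter (default 200 cells/mm² — a realistic detection density for
melanoma at 20×) in a rectangle (default 6 × 3 mm) or smoothed-blob
tumor with an epidermis strip on the superficial edge; per-marker
two-component log-normal intensities (defaults: background ln-mean 1.0,
expressing ln-mean 3.0, both ln-sd 0.5 — a 4-sd separation — with
Ki67+ fraction 0.30 and S100+ fraction 0.60, typical of a proliferating
melanoma); normal nucleus areas (40 ± 8 µm²) with a configurable
per-band mean shift. Latent labels, true depth and true band go to a
sidecar table the pipeline never reads. `generate_cohort` draws
survival from a Weibull proportional-hazards model
S(t|x) = exp(−(t/scale)^shape · e^{β·x}) (scale 60 months, shape 1.2)
with independent exponential censoring whose rate is calibrated by
root-finding so the expected censored fraction matches the request.
`generate_study` ties the two levels together: a latent per-patient
standard-normal score shifts that patient's invasive-band nucleus areas
(6 µm²/sd) and multiplies the hazard (0.8 log-hazard/sd), with
patient-to-patient variation in tumor depth/width (15% cv) so estimated
thickness is a live factor.

What the simulator does *not* reproduce: spatially correlated marker
expression, cell clustering and exclusion zones, segmentation errors,
batch/staining variation across slides, correlated clinical covariates
(thickness and mitosis are independent of the planted morphology score,
so the demo's thickness–nuclei-size correlation is null by design,
unlike real cohorts), and multi-fragment or highly concave tumors.
Passing tests therefore demonstrate that the *computational chain* is
correct and recovers planted structure under its stated model — not
that the biological findings transfer to any particular cohort.

## Problem sizes and numerical choices

Defaults were chosen so a desk-scale run is comfortable: 10 µm raster
(vs the 0.5 µm scan pixel), 256 Otsu bins, B = 1000 bootstrap
replicates (the bundled demo config uses B = 300 and 40 patients;
results are insensitive to B beyond a few hundred). The acceptance
script uses 100 replicates of n = 400 for β-recovery and coverage, ten
n = 200 cohorts for the null concordance level, and the 40-patient demo
study end-to-end. All randomness flows from per-call
`numpy.random.Generator` seeds; reruns with the same seed are
byte-identical. Degenerate inputs fail loudly: all-equal intensities,
collinear boundary points, sliver tumors (raster of zero pixels),
constant covariates, zero comparable pairs.
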