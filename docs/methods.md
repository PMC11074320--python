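# Methods

## Accounting model

Provincial crop-farming emissions are activity-based: for region *r*, year
*y*,

E(r, y) = Σₐ Σ_g A(r, y, a) · EF(a, g) · GWP(g)

over the six activity categories `residue_open_burning`, `rice_cultivation`,
`cropland_emissions`, `machinery_use`, `n_fertilizer_production`,
`pesticide_production` and gases CO₂, CH₄, N₂O. The model assumes emissions
are linear in activity amounts — the standard emission-factor assumption —
and excludes land-use-change, peat-drainage/burning and forest-product
emissions, whose activity data are far more uncertain. Intensity is
I(r, y) = E(r, y) / area(r) in ton CO₂-eq/km², which makes regions of very
different sizes comparable and is the quantity downscaled.

**Emission factors** are user configuration. The shipped table
(`cropcarbon.config.PLACEHOLDER_EMISSION_FACTORS`) is a placeholder —
unit-consistent and order-of-magnitude plausible, not the factors of any
published scheme; analyses of real data must substitute the factors of the
accounting scheme being followed. The factor schema permits any (activity,
gas) pairing rather than hard-coding which gases each activity emits.
**GWPs** default to the 100-yr AR4 values (CH₄ 25, N₂O 298), the convention
of the long-running inventory literature this pipeline interoperates with;
they are overridable everywhere and echoed in logs and manifests, since
switching to AR5/AR6 values rescales CH₄- and N₂O-dominated activities.

## Indicator screening

All (province, year) rows are pooled into one random-forest regression of
intensity on the candidate per-area indicators (pooling matches the use of a
single national screening; a per-window screen is a config choice upstream
of this library — pass a row subset). Importances are impurity-decrease
values rescaled to sum to 100%, the default of mainstream forest
implementations; permutation importance is available behind
`method="permutation"` but is not the default. Selection takes the shortest
importance-descending prefix whose cumulative share reaches a threshold,
default 0.95; ties are broken lexicographically by indicator name for
determinism. The threshold rule is adopted because, applied to the reference
importance profile of the 12 provincial indicators
(`screen.REFERENCE_IMPORTANCE_PCT`), it reproduces exactly the four
proxy-backed indicators at 95.76% cumulative share. Forest defaults: 500
trees, p/3 features per split (the regression convention), seed recorded in
the report metadata.

## Downscaling and the mass-balance constraint

The downscaling forest is trained on pooled provincial rows (intensity ~
selected covariates). Evaluation follows a 90/10 random hold-out — |test| =
round(0.1·n) — plus 10-fold shuffled cross-validation on the training rows;
R² = 1 − SS_res/SS_tot and RMSE are reported for train, CV mean and test.
Leave-one-out is available as `cv="loo"` (R² computed on pooled held-out
predictions, since per-fold R² is undefined at fold size 1). A zero-variance
evaluation target makes R² undefined; it is returned as NaN with RMSE still
computed, rather than raising, so degenerate folds do not abort a run.

County predictions inherit the forest's range-boundedness: predictions are
convex combinations of training targets, so non-negative training
intensities guarantee non-negative county intensities. Counties whose
covariates are all zero get whatever the forest predicts — there is no
special-casing of zero-cropland counties, only a log warning — because any
rule here would be arbitrary.

The provincial constraint is multiplicative: one factor per (province,
year), f = E_prov / Σ_c Î_c·area_c, applied to every county intensity in
that province-year. This conserves the provincial total exactly (the
implementation verifies < 1e-6 relative error end-to-end and achieves
machine precision), preserves within-province county ranking, and cannot
produce negative intensities — the reason additive redistribution was
rejected. A zero provincial total zeroes the counties with factor 0; a zero
raw sum against a non-zero total is a hard error since no multiplicative
factor exists. The model predicts intensity, not total emissions; county
totals are always derived through county areas. Pooling all years into one
model is the default (per-year models can be fit by passing year subsets).

Targets are used on their natural scale (no normalization); published
diagnostics of comparable downscaling models sometimes imply a normalized
target scale (RMSE ~1e-4), so RMSE magnitudes are only comparable within one
scale convention.

## Validation diagnostics

Zonal extraction consumes an explicit cell→county area-weight lookup instead
of GIS polygon intersection: the weighted mean per county, with NaN cells
treated as no-data and fully-uncovered counties omitted with a log entry.
Comparison between county products uses Pearson r plus the R² of the simple
linear fit of the reference on our values — with one predictor this R²
equals r² in either fit direction, so the direction convention is
immaterial — and reports mean bias (ours − reference). Spearman rank
correlation is deliberately not used; the agreement claim is about linear
association of intensities. The national series aggregates provincial totals
per year and divides by total land area (area-weighted mean intensity).

## Synthetic worlds

The generator emulates the pipeline's three inputs with a known generative
link. Defaults — the study conditions for all end-to-end tests — are 15
provinces × 20 counties × 10 years (2000–2009). County areas are log-normal
(median 2 000 km², log-sd 0.4); province area is exactly the sum of its
county areas. Each of 12 candidate covariates is a product of log-normal
effects: a static province effect (log-sd 0.3), a province-year effect
(log-sd 0.4) and a county-year idiosyncratic term (log-sd 0.15). True county
intensity is a monotone linear link over the 4 informative covariates
(intercept 5; coefficients 40, 35, 30, 25) times multiplicative log-normal
noise with mean 1 and CV 0.05 — multiplicative because intensities are
strictly positive. The 8 nuisance covariates are generated independently of
intensity. Provincial indicators are exact area-weighted county means;
activity amounts are back-derived through the synthetic factor table so the
inventory reproduces the sum of true county emissions exactly; the reference
product is truth times independent log-normal noise (CV 0.10). All
parameters and the seed are echoed in a manifest, and regeneration with the
same seed is bit-identical.

The variance split matters and was designed to the generator's contracts: a
dominant *static* province effect makes every covariate — informative or
not — a proxy for province identity, collapsing the effective sample to the
number of provinces and letting nuisance indicators acquire spurious
importance; a substantial province-year effect keeps the 150 provincial rows
close to independent draws. The county-level log-sd is kept moderate so
county covariates do not extrapolate far beyond the provincial range the
forest was trained on. With these settings the 4 informative indicators
occupy the top 4 ranks in ≈96% of seeded runs and the full pipeline recovers
county ground truth with R² ≈ 0.92 (R² ≈ 0.95 with the noise switched off).

What the generator does *not* emulate: spatial autocorrelation between
neighbouring counties, realistic magnitudes of any real country's emissions,
reporting gaps, or indicator collinearity structures found in real
yearbooks. Passing tests therefore demonstrate correctness of the
*procedure* (accounting algebra, selection rule, split/CV wiring, exact mass
balance, recovery under a known monotone link), not the accuracy of any real
county product.

## Numerical choices and degenerate inputs

- Importances are rescaled to sum to 100 within 1e-6; an all-zero importance
  vector (possible only for a constant target, which is rejected earlier) is
  a hard error.
- Selection uses a 1e-9 slack when comparing cumulative shares to the
  threshold so a threshold equal to an attainable share (e.g. 0.9576)
  selects that prefix despite float rounding.
- The mass-balance audit uses relative error against the provincial total;
  conservation holds to machine epsilon because the factor is applied
  exactly once per county.
- Missing (region, year) rows are simply absent from inventory output; no
  interpolation is performed.
- Random splits, forests and worlds all consume explicit integer seeds;
  nothing reads global random state.

## Problem sizes

Default test and reproduction sizes are the generator defaults (150
provincial rows, 3 000 county-years); the mass-conservation sweep uses 100
worlds of 4 provinces × 5 counties × 3 years with 30-tree forests, and the
screening-fidelity sweep 50 seeded default-size worlds — sizes at which every
quantity is stable across seeds while a full reproduction run stays around a
minute on one CPU.

## Known limitations

- Emission factors are placeholders; no claim is made about real-world
  magnitudes until a user supplies a published factor set.
- The downscaling model is only as good as the covariate-intensity link at
  the provincial scale; the constraint guarantees provincial consistency,
  not county-level accuracy beyond what the covariates carry.
- Forest predictions cannot extrapolate beyond the training target range, so
  counties far outside the provincial covariate distribution are clamped
  toward provincial extremes before adjustment.
- Uncertainty intervals on county estimates are out of scope.
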