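# Methods

## The decomposition model

Bulk soil organic matter is treated as `n ∈ {1, 2, 3}` parallel, independent
pools. Pool *i* holds an initial fraction *fᵢ* of the stock *S(0)*
(mg C g⁻¹ soil) and decays first-order at a reference rate *kᵢ* (d⁻¹), giving
the remaining substrate S(t) = S(0)·Σ fᵢ e^(−kᵢt) with Σ fᵢ = 1, cumulative
CO₂-C release R_cum(t) = S(0) − S(t), and instantaneous flux
R(t) = S(0)·Σ kᵢ fᵢ e^(−kᵢt). The model carries the standard assumptions:
pools do not exchange carbon, rates are constant over the incubation (no
temperature/moisture modifiers — those belong to the ecosystem-model layer,
not to this package), and all respired C derives from the initial stock.
Pools are stored canonically fast→slow (k₁ > k₂ > k₃); any permutation of a
fitted solution is mapped back to this order.

## Fitting

Fitting minimizes the residual sum of squares of modeled vs observed
cumulative release (flux optional) with damped Gauss–Newton
(Levenberg–Marquardt, `scipy.optimize.least_squares(method="lm")`). The
constraints are removed by reparameterization rather than handled at bounds:

* rates: log k₁ is free; each subsequent log kᵢ is the previous minus a
  softplus-transformed gap, so the ordering k₁ > k₂ > k₃ and positivity hold
  identically;
* fractions: stick-breaking on logits, so fᵢ ∈ (0,1) and Σ fᵢ = 1 exactly;
* S(0): fixed when supplied (e.g. from measured SOC), otherwise fitted as a
  log-parameter.

Convergence is declared at a relative RSS change below 1e-10 or 500
iterations. The optimizer multi-starts from 24 deterministic points: ordered
rate combinations drawn from a log-spaced grid over [1e-6, 1] d⁻¹ with
fractions at the simplex centroid; a start achieving an essentially zero RSS
short-circuits the remaining starts. Degenerate inputs (all-zero or
non-monotone cumulative series) are fitted anyway and flagged; rates that
collapse to the numerical floor (1e-9 d⁻¹) are flagged `k_at_lower_bound`; a
fit whose slowest rate satisfies duration · k < 0.05 is flagged as
under-identified, since that pool barely expresses itself in the observation
window. R², RMSE and the SSE-based AIC/BIC are computed from the residuals;
p is the number of free parameters of the transformed problem.

Measured respiration series can be fitted against cumulative release (the
default — most compiled rate estimates derive from cumulative CO₂) or against
the instantaneous flux; both observables share the same parameterization.

## Evaluation metrics

The metrics module implements the definitional forms used for model
selection, not library defaults: R² = 1 − SSE/TSS (negative for predictors
worse than the mean), the concordance correlation coefficient with raw sums
of squares (no n−1 correction; the denominator is n·(ȳ_sim − ȳ_obs)² plus the
two centered sums of squares), RMSE, RMSEn = RMSE / IQR(observations), and
AIC = n·ln(SSE/n) + 2p. This AIC is the only one used to compare predictive
models. Quantiles everywhere use linear interpolation of order statistics
(the "type 7" convention); 90% intervals are the 5–95 percentile range and
50% intervals the 25–75 range. The Kruskal–Wallis test is the tie-corrected
rank H with a chi-square null (checked in the tests against an exhaustive
permutation null); Spearman matrices are pairwise-complete, with constant
columns reported as undefined (NaN with a warning), never silently zero.

## Dataset layer

The compiled-table schema holds one fitted incubation record per row: site
coordinates (WGS84 decimal degrees), Elev, MAP, MAT, ecosystem, texture
(Sand+Silt+Clay ≈ 100 within a tolerance of 2 for source rounding), pH,
moisture, IncT, duration, measured-variable tag, model variant (M1/M2/M3),
fractions, rates (harmonized to d⁻¹; yr⁻¹ inputs divide by 365), fit
diagnostics, MBC, SOC, NDVI, Slope. Missing values are empty cells. The
closing fraction is derived on load (f2 = 1 − f1 for M2, f3 = 1 − f1 − f2 for
M3). Rows failing validation go to a reject report with row numbers and
reasons. Gap filling samples covariate rasters at the nearest cell center and
marks filled entries with a `*_gap_filled` flag; sites outside a raster's
extent stay missing. The reference-model table carries the fixed per-pool
rates of ANIMO (5.5e-3, 6.0e-4), DAISY (5.0e-2, 5.0e-3), CLMcn (7.1e-2,
1.4e-3, 1.0e-4) and DAYCENT (3.0e-2, 1.1e-3, 9.0e-6) d⁻¹, checked against the
50% CI of the summarized table.

## Predictive modelling

Rates span several orders of magnitude and are regressed as log10(k);
fractions are regressed raw. All reported metrics are computed on the model
scale (log10 for rates), where R² is meaningful across the full dynamic
range. The workflow per target:

* 75/25 train/test partition, stratified on five y-quantile bins (simple
  random with a warning when too few rows);
* optional recursive feature elimination: backward elimination guided by
  model importance (|standardized coefficient| for MLR), each subset size
  scored by 10-fold CV R²; subsets within 0.01 of the best tie, and the
  smallest tied subset wins — under a pure-noise target nothing clears the
  threshold and the single best feature is returned;
* hyperparameter grids under repeated 10-fold CV (3 repeats): GBM over
  n_estimators {10, 50, 100, 150, 200} × depth 1–7 × learning rate
  {0.01, 0.1} with min node size 10; RF fixed at 100 trees with mtry from 2
  to p−1; MLR has no grid;
* optional repeated restarts with fresh partition seeds, keeping the run with
  the best held-out R²;
* final comparison across methods by the SSE-based AIC with p = number of
  selected features, computed on the shared held-out set (models evaluated on
  different sets refuse to compare).

Variable importance is permutation importance on the held-out set for RF/GBM
(clipped at zero) and |standardized coefficients| for MLR, normalized to sum
to 100%. Partial dependence clamps one feature to a grid spanning its
observed range, averages predictions over the data, and reports the x-axis
both raw and normalized to 0–1.

## Mapping and uncertainty

Rasters are plain lat/lon grids, rows north→south, cell-center convention,
NaN for nodata; I/O is a self-describing plain-text format plus NetCDF3
(via xarray's scipy engine). Bilinear resampling interpolates on cell
centers; any contributing nodata cell propagates nodata, and target centers
in the half-cell fringe are clamped to the source center hull. The default
analysis extent is 60°S–90°N, where global soil-property products end.

Gridded prediction stacks co-registered feature rasters into a cell table and
applies the trained model, so grid predictions are bit-identical to tabular
ones. Relative uncertainty is ReUn = Width₉₀%CI / Mean:

* input (pH) uncertainty: the width is |prediction at the 95th-percentile pH
  layer − prediction at the 5th|, the denominator the prediction at the mean
  layer; if pH was eliminated by feature selection, ReUn is identically 0;
* structure uncertainty: the width is the empirical 5–95 percentile range of
  the individual RF trees' predictions, the denominator the ensemble mean.

Because the response need not be monotone in pH, and back-transformed
per-tree predictions are right-skewed, the bound layers are widened (never
narrowed) where needed so that lower ≤ mean ≤ upper holds cellwise, while the
ReUn width keeps its definition. Cells with non-positive mean predictions are
masked (counted and warned), never clipped. Latitudinal profiles aggregate
each band (default 0.5°) across longitude into a mean and 5–95 percentile
interval; means are unweighted by default, with a cos(latitude) area-weighted
option.

## The synthetic world

The generator defines the study conditions under which the pipeline is
tested; it emulates the structure of a compiled incubation synthesis, not any
particular dataset.

* **Covariates** come from an 11-dimensional Gaussian copula whose latent
  correlations reproduce the two strong empirical rank dependences of such
  compilations — Spearman ρ(MAP, MAT) = 0.822 and ρ(Elev, Slope) = −0.775 —
  with all other pairs independent (r = 2·sin(πρ/6) converts the targets;
  infeasible matrices are repaired to the nearest PSD with a warning).
  Marginals are fixed, analytic quantile maps: MAP 0–4000 mm (right-skewed),
  MAT −15–30 °C, Sand 5–95 %, Clay a fraction of the non-sand remainder (so
  texture sums to 100 exactly), pH 3.5–9.5, SOC 1–100 g kg⁻¹ (log-uniform),
  MBC 10–1000 g C m⁻², Elev 0–5000 m, Slope 0–45°, NDVI 0–1, IncT 5–35 °C.
* **Parameters** follow a known additive map on covariate quantiles:
  log10 kᵢ = log10(median intercept) + Σ weight·shape(u) + N(0, 0.15). The
  intercepts are the field's median estimates (M2: 0.12 and 1.1e-3 d⁻¹; M3:
  0.029, 6.8e-4 and 1.06e-5 d⁻¹), so generated medians land inside the
  observed 90% intervals by construction. Component shapes are smooth
  (tanh ridge, sine wave, mid-range arch); each rate has one designated
  dominant covariate — Sand for the fast pool, MAP for the slow pool, pH for
  the passive pool — whose component mixes a monotone and an oscillatory part
  so that tree ensembles, not linear regression, can recover it. Fractions
  come from a stick-breaking logistic map (noise SD 0.3 on logits) centered
  near 2.6% (M3-f1) and 32% (M3-f2). All components are retrievable for
  partial-dependence and importance oracles.
* **Series** are exact cumulative curves with truncated-Gaussian noise on the
  release increments (default fraction 0.02), re-cumulated, so noisy curves
  stay monotone like real chamber data. Real measurement-noise structure is
  unreported in incubation sources; this noise model is a stated assumption.
* **Rasters** are latitudinal gradients plus seeded smooth spatial noise
  sharing the tabular marginals; MAP tracks MAT and Slope opposes Elev. pH is
  emitted with 5%/95% percentile layers at ±0.6 pH units. `gen_world` samples
  a site table directly off the rasters so the tabular and spatial paths share
  one source of truth. The generator makes no attempt to emulate the spatial
  autocorrelation of real soil/climate products.

What passing tests show — and what they do not: recovery results demonstrate
that the estimators are correct and well-conditioned under these conditions
(independent additive effects, known noise, no measurement bias). Real
compiled datasets have wider parameter spread, heteroscedastic and source-
dependent errors, spatial clustering of sites, and covariate maps that are
not additive; held-out R² on real data is expected to be lower, and the
reference-model-within-CI fractions reported by the acceptance script are
tighter than a literature synthesis would give because the synthetic spread
is narrower than the literature's.

## Problem sizes and numerical choices

The default synthetic benchmark uses n = 800 sites, 20 seeds, a fixed-mtry
(4) 100-tree RF against MLR, and 5-fold CV — sizes chosen so the whole suite
and the acceptance script run comfortably on a single CPU while leaving the
statistical conclusions (RF ≫ MLR, dominant covariate ranked first) far from
their thresholds. Incubation fits use 60 points over 365 d; mapping checks
use 24×48 to 30×60 grids with 5–7.5° latitude bands. The full-scale
protocol (100 restarts, full GBM grid, repeated 10-fold CV ×3, 1-km rasters)
is available through the same interfaces by changing configuration values.

Tolerances: forward-model conservation holds to 1e-12 relative; noiseless
recovery is asserted at 0.1% relative (observed ~1e-13); fraction sums to
1e-9; texture sums exactly. Ties in RFE break toward parsimony; pool order
ties are broken by a 1e-9 relative rate separation.

## Known limitations

* Three-pool fits with the slowest pool barely expressed in the incubation
  window are intrinsically under-identified; the package flags rather than
  regularizes them.
* The SSE-based AIC is not a likelihood AIC; it is used only for relative
  ranking on a shared evaluation set.
* GeoTIFF I/O is not provided; rasters move through the plain-text format or
  NetCDF3.
* No spatial cross-validation: site clustering in real compilations will make
  random-split held-out R² optimistic.
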