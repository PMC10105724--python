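# somkin

Multi-pool first-order soil organic matter (SOM) decomposition kinetics:
constrained fitting of incubation CO₂ time series, synthesis-table
summarization, machine-learning prediction of kinetics parameters from
edaphic-climatic covariates, and gridded global-style mapping with relative
uncertainty.

## Who this is for

Soil biogeochemists and land-surface modellers who work with laboratory
incubation data. Earth system models represent SOM decomposition with a few
conceptual pools (fast, slow, passive) decaying by first-order kinetics, each
with a reference rate k_ref that is usually treated as a global constant.
Incubation syntheses show k_ref varies by orders of magnitude with soil
texture, pH, and climate. `somkin` implements the full chain from raw
incubation curves to spatial predictions of pool sizes and rates.

## The model

Bulk SOM is `n` parallel pools (n ∈ {1, 2, 3}); pool *i* holds an initial
fraction *fᵢ* of the stock *S(0)* and decays at rate *kᵢ* (d⁻¹):

    S(t)     = S(0) · Σᵢ fᵢ e^(−kᵢ t),          Σᵢ fᵢ = 1
    R_cum(t) = S(0) · (1 − Σᵢ fᵢ e^(−kᵢ t))      (cumulative CO₂-C release)
    R(t)     = S(0) · Σᵢ kᵢ fᵢ e^(−kᵢ t)         (instantaneous flux)

Fitting an observed series is a constrained nonlinear least-squares problem
(fractions on the simplex, rates positive and strictly ordered fast→slow).
`somkin` solves it with damped Gauss–Newton (Levenberg–Marquardt) in an
unconstrained reparameterization — ordered log-rates via cumulative softplus
gaps, fractions via stick-breaking — with deterministic multi-start over a
log-spaced rate grid.

Downstream, the eight parameters of the two- and three-pool variants
(M2-k1, M2-k2, M2-f1, M3-k1, M3-k2, M3-k3, M3-f1, M3-f2) are regressed on
eleven covariates (MAP, MAT, Sand, Clay, pH, SOC, MBC, Elev, Slope, NDVI,
IncT) with MLR / GBM / RF, recursive feature elimination, repeated 10-fold
CV, and model selection by the SSE-based AIC

    AIC = n · ln(SSE/n) + 2p,

with agreement measured by R², the concordance correlation coefficient ρ_c,
RMSE and IQR-normalized RMSEn. Trained models are applied cellwise over
covariate rasters; relative uncertainty ReUn = Width₉₀%CI / Mean is propagated
from pH percentile layers (input uncertainty) and from the spread of
individual RF trees (structure uncertainty), then aggregated into latitudinal
profiles.

## Worked example

Fit a two-pool model to a noiseless synthetic incubation series and read the
parameters back:

```python
import numpy as np
from somkin import PoolKinetics, MultiPoolKineticsModel, cumulative_release

true = PoolKinetics(f=[0.2, 0.8], k=[0.05, 0.005], s0=1.0)
t = np.linspace(1, 365, 60)                 # days
y = cumulative_release(true, t)             # mg C g^-1 soil

m = MultiPoolKineticsModel(n_pools=2, s0=1.0).fit(t, y)
print("k =", m.k_, " f =", m.f_, " R2 =", m.result_.r2)
```

prints

```
k = [0.05  0.005]  f = [0.2 0.8]  R2 = 1.0
```

i.e. the fast pool (20% of the stock) turns over at 0.05 d⁻¹ and the slow
pool (80%) at 0.005 d⁻¹, exactly the generating values, with a perfect fit.

Train a random forest on a synthetic compiled table and rank the drivers of
the passive-pool rate:

```python
from somkin import SyntheticConfig, gen_covariates, true_parameter_map, ml

cfg = SyntheticConfig(n_sites=800)
X = gen_covariates(cfg, seed=0)[ml.COVARIATES]
y = true_parameter_map(X, cfg, seed=1)["k3"].to_numpy()

model = ml.train_model(X, y, method="rf", target_name="M3_k3",
                       rfe=False, seed=0)
print(round(model.test_metrics["r2"], 2))
print(ml.variable_importance(model, seed=0).nlargest(3).round(1))
```

prints

```
0.82
pH     88.6
MAP     8.5
SOC     2.0
```

— the held-out R² on log10 k3 is 0.82 and pH dominates the ranking, which is
exactly the structure the synthetic generator encodes (pH is the designated
driver of the passive pool).

The same workflow is available from the shell: `somkin fit`, `somkin
summarize`, `somkin train`, `somkin importance`, `somkin pdp`, `somkin map`,
`somkin simulate`, and `somkin run --config cfg.toml` for the whole pipeline.

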