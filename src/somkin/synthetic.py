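"""Seeded synthetic inputs: covariate tables, kinetics parameters, incubation
curves and covariate rasters.

The generator emulates the structure of a compiled laboratory-incubation
synthesis so every pipeline stage is testable without downloads:

* covariates are drawn through a Gaussian copula reproducing the two strong
  empirical rank correlations of such datasets (Spearman rho(MAP, MAT) = 0.822
  and rho(Elev, Slope) = -0.775; all other pairs ~ 0) with realistic marginals;
* true kinetics parameters follow a known additive map: log10 k_i is an
  intercept (the field's median estimate for that pool) plus weighted smooth
  component functions of covariate quantiles plus Gaussian noise, with one
  designated dominant covariate per parameter (Sand -> fast pool, MAP -> slow
  pool, pH -> passive pool); fractions come from a stick-breaking logistic map;
* incubation series are exact multi-exponential cumulative curves with
  truncated-Gaussian noise added on the release increments (cumulative curves
  stay monotone, like real chamber data);
* rasters are latitudinal gradients plus seeded smooth spatial noise sharing
  the tabular marginals, with 5%/95% percentile layers for pH.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .kinetics import IncubationSeries, PoolKinetics, cumulative_release
from .mapping import Raster
from .ml import COVARIATES

__all__ = [
    "SyntheticConfig", "gen_covariates", "true_parameter_map",
    "gen_incubation_series", "gen_rasters", "gen_world", "gen_kinetics_table",
    "component_function", "covariate_quantiles", "true_parameter_raster",
]

# median (intercept) and 90% CI of log10 k per pool, by model variant;
# intercepts sit at the field's median estimates so generated medians fall
# inside the observed ranges by construction
K_MEDIANS = {
    "M2": {"k1": 0.12, "k2": 1.1e-3},
    "M3": {"k1": 0.029, "k2": 6.8e-4, "k3": 1.06e-5},
}
K_CI90 = {
    "M2": {"k1": (3.7e-3, 0.59), "k2": (5.02e-5, 2.0e-2)},
    "M3": {"k1": (4.2e-3, 0.50), "k2": (1.21e-4, 3.8e-2),
           "k3": (5.3e-7, 7.0e-4)},
}

# ---------------------------------------------------------------------------
# marginals: value = Q(u) with analytic inverse, u the copula quantile
# ---------------------------------------------------------------------------

def _q_map(u):       return 4000.0 * u ** 2          # mm, right-skewed
def _q_map_inv(x):   return np.sqrt(np.clip(x, 0, 4000) / 4000.0)
def _q_mat(u):       return -15.0 + 45.0 * u         # degC
def _q_mat_inv(x):   return np.clip((x + 15.0) / 45.0, 0, 1)
def _q_sand(u):      return 5.0 + 90.0 * u           # %
def _q_sand_inv(x):  return np.clip((x - 5.0) / 90.0, 0, 1)
def _q_ph(u):        return 3.5 + 6.0 * u
def _q_ph_inv(x):    return np.clip((x - 3.5) / 6.0, 0, 1)
def _q_soc(u):       return 10.0 ** (2.0 * u)        # g kg^-1, log-uniform 1-100
def _q_soc_inv(x):   return np.clip(np.log10(np.clip(x, 1, 100)) / 2.0, 0, 1)
def _q_mbc(u):       return 10.0 ** (1.0 + 2.0 * u)  # g C m^-2, 10-1000
def _q_mbc_inv(x):   return np.clip((np.log10(np.clip(x, 10, 1000)) - 1) / 2, 0, 1)
def _q_elev(u):      return 5000.0 * u ** 2          # m
def _q_elev_inv(x):  return np.sqrt(np.clip(x, 0, 5000) / 5000.0)
def _q_slope(u):     return 45.0 * u ** 1.5          # degrees
def _q_slope_inv(x): return np.clip(x / 45.0, 0, 1) ** (2.0 / 3.0)
def _q_ndvi(u):      return u
def _q_ndvi_inv(x):  return np.clip(x, 0, 1)
def _q_inct(u):      return 5.0 + 30.0 * u           # degC
def _q_inct_inv(x):  return np.clip((x - 5.0) / 30.0, 0, 1)

_MARGINALS = {
    "MAP": (_q_map, _q_map_inv), "MAT": (_q_mat, _q_mat_inv),
    "Sand": (_q_sand, _q_sand_inv), "pH": (_q_ph, _q_ph_inv),
    "SOC": (_q_soc, _q_soc_inv), "MBC": (_q_mbc, _q_mbc_inv),
    "Elev": (_q_elev, _q_elev_inv), "Slope": (_q_slope, _q_slope_inv),
    "NDVI": (_q_ndvi, _q_ndvi_inv), "IncT": (_q_inct, _q_inct_inv),
}


def _clay_from_u(u_clay, sand):
    # clay takes a fraction of the non-sand remainder; Sand+Silt+Clay == 100
    return (100.0 - sand) * (0.05 + 0.85 * u_clay)


def _clay_to_u(clay, sand):
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (clay / (100.0 - sand) - 0.05) / 0.85
    return np.clip(u, 0, 1)


def covariate_quantiles(df: pd.DataFrame) -> pd.DataFrame:
    """Map covariate values back to their marginal quantiles u in [0, 1]."""
    out = {}
    for name in COVARIATES:
        if name == "Clay":
            out[name] = _clay_to_u(df["Clay"].to_numpy(float),
                                   df["Sand"].to_numpy(float))
        else:
            out[name] = _MARGINALS[name][1](df[name].to_numpy(float))
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# component shapes (smooth functions of the quantile u, roughly zero-mean)
# ---------------------------------------------------------------------------

def _shape_ridge(u):  return np.tanh(4.0 * (u - 0.5))
def _shape_wave(u):   return np.sin(2.0 * np.pi * u)
def _shape_arch(u):   return 1.0 / 3.0 - 4.0 * (u - 0.5) ** 2  # peak mid-range

_SHAPES = {"ridge": _shape_ridge, "wave": _shape_wave, "arch": _shape_arch}

# default dominance structure: (covariate, weight, shape) per target.
# Dominant components mix a monotone and an oscillatory part (ridge + wave)
# so tree ensembles, not linear regression, recover them.
_DEFAULT_COMPONENTS = {
    "M2_k1": [("Sand", 0.45, "ridge"), ("Sand", 0.45, "wave"),
              ("MBC", 0.18, "ridge")],
    "M2_k2": [("pH", 0.45, "arch"), ("pH", 0.40, "wave"),
              ("NDVI", 0.15, "ridge"), ("MAP", 0.12, "ridge")],
    "M2_f1": [("NDVI", 0.8, "ridge"), ("SOC", 0.25, "wave")],
    "M3_k1": [("Sand", 0.45, "ridge"), ("Sand", 0.45, "wave"),
              ("Clay", 0.15, "ridge"), ("MBC", 0.12, "ridge")],
    "M3_k2": [("MAP", 0.45, "wave"), ("MAP", 0.40, "ridge"),
              ("Clay", 0.15, "ridge"), ("Slope", 0.12, "ridge")],
    "M3_k3": [("pH", 0.50, "arch"), ("pH", 0.45, "wave"),
              ("MAP", 0.18, "ridge"), ("SOC", 0.10, "ridge")],
    "M3_f1": [("SOC", 0.8, "ridge"), ("NDVI", 0.25, "wave")],
    "M3_f2": [("MAT", 0.7, "ridge"), ("MAP", 0.25, "wave")],
}

# stick-breaking logit intercepts for pool fractions
_F_LOGITS = {"M2_f1": -2.2, "M3_f1": -3.6, "M3_f2": -0.7}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    ``noise_sd_log10k`` is the irreducible SD (decades) on log10 rates;
    ``noise_sd_logit_f`` the SD on fraction logits; ``series_noise_fraction``
    the relative SD on incubation release increments.
    """

    n_sites: int = 800
    pool_model: str = "M3"
    rho_map_mat: float = 0.822
    rho_elev_slope: float = -0.775
    noise_sd_log10k: float = 0.15
    noise_sd_logit_f: float = 0.3
    series_noise_fraction: float = 0.02
    components: dict = field(default_factory=lambda: dict(_DEFAULT_COMPONENTS))
    ph_spread: float = 0.6          # half-width of the pH 5-95% band (pH units)
    seed: int | None = None


def component_function(config: SyntheticConfig, target: str, covariate: str):
    """The generator's additive component for (target, covariate), as a
    callable of the covariate quantile u in [0, 1] (weights applied)."""
    terms = [(w, _SHAPES[s]) for c, w, s in config.components[target]
             if c == covariate]
    if not terms:
        raise KeyError(f"{covariate!r} has no component for {target!r}")
    return lambda u: sum(w * f(np.asarray(u, float)) for w, f in terms)


def dominant_covariate(config: SyntheticConfig, target: str) -> str:
    """Covariate with the largest total component weight for a target."""
    tot = {}
    for c, w, _ in config.components[target]:
        tot[c] = tot.get(c, 0.0) + abs(w)
    return max(tot, key=tot.get)


# ---------------------------------------------------------------------------
# covariate table (Gaussian copula)
# ---------------------------------------------------------------------------

def _copula_corr(config) -> np.ndarray:
    """Pearson correlation of the latent Gaussian reproducing the target
    Spearman correlations (r = 2 sin(pi * rho / 6))."""
    p = len(COVARIATES)
    C = np.eye(p)
    def put(a, b, rho):
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        i, j = COVARIATES.index(a), COVARIATES.index(b)
        C[i, j] = C[j, i] = r
    put("MAP", "MAT", config.rho_map_mat)
    put("Elev", "Slope", config.rho_elev_slope)
    w = np.linalg.eigvalsh(C)
    if w.min() < 1e-10:  # nearest-PSD repair by eigenvalue clipping
        import warnings
        warnings.warn("correlation matrix repaired to nearest PSD")
        vals, vecs = np.linalg.eigh(C)
        C = vecs @ np.diag(np.clip(vals, 1e-10, None)) @ vecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def gen_covariates(config: SyntheticConfig, seed=None) -> pd.DataFrame:
    """Sample the eleven-covariate table through the Gaussian copula.

    Sand + Silt + Clay == 100 exactly (Silt is carried as an extra column).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    C = _copula_corr(config)
    z = rng.multivariate_normal(np.zeros(len(COVARIATES)), C,
                                size=config.n_sites, method="cholesky")
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    df = pd.DataFrame(index=range(config.n_sites))
    for j, name in enumerate(COVARIATES):
        if name == "Clay":
            continue
        df[name] = _MARGINALS[name][0](u[:, j])
    df["Clay"] = _clay_from_u(u[:, COVARIATES.index("Clay")],
                              df["Sand"].to_numpy())
    df["Silt"] = 100.0 - df["Sand"] - df["Clay"]
    return df[COVARIATES + ["Silt"]]


# ---------------------------------------------------------------------------
# true parameter map
# ---------------------------------------------------------------------------

def _target_signal(config, target, uq: pd.DataFrame) -> np.ndarray:
    s = np.zeros(len(uq))
    for cov, w, shape in config.components[target]:
        s += w * _SHAPES[shape](uq[cov].to_numpy())
    return s


def true_parameter_map(covariates: pd.DataFrame, config: SyntheticConfig,
                       seed=None, noise: bool = True) -> pd.DataFrame:
    """True kinetics parameters per site under the configured additive map.

    Rates: log10 k = log10(median intercept) + signal + N(0, noise_sd).
    Fractions: stick-breaking logistic map on logit intercept + signal + noise.
    Columns follow the model variant in ``config.pool_model``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    uq = covariate_quantiles(covariates)
    n = len(covariates)
    m = config.pool_model
    out = pd.DataFrame(index=covariates.index)
    sd_k = config.noise_sd_log10k if noise else 0.0
    sd_f = config.noise_sd_logit_f if noise else 0.0
    for pool, med in K_MEDIANS[m].items():
        t = f"{m}_{pool}"
        log10k = np.log10(med) + _target_signal(config, t, uq) \
            + rng.normal(0.0, sd_k, n) * (1.0 if noise else 0.0)
        out[pool] = 10.0 ** log10k
    # stick-breaking fractions
    def _sig(x):
        return 1.0 / (1.0 + np.exp(-x))
    if m == "M2":
        z1 = _F_LOGITS["M2_f1"] + _target_signal(config, "M2_f1", uq) \
            + rng.normal(0.0, sd_f, n)
        out["f1"] = _sig(z1)
        out["f2"] = 1.0 - out["f1"]
    else:
        z1 = _F_LOGITS["M3_f1"] + _target_signal(config, "M3_f1", uq) \
            + rng.normal(0.0, sd_f, n)
        z2 = _F_LOGITS["M3_f2"] + _target_signal(config, "M3_f2", uq) \
            + rng.normal(0.0, sd_f, n)
        out["f1"] = _sig(z1)
        out["f2"] = (1.0 - out["f1"]) * _sig(z2)
        out["f3"] = 1.0 - out["f1"] - out["f2"]
    return out


# ---------------------------------------------------------------------------
# incubation series
# ---------------------------------------------------------------------------

def gen_incubation_series(params: PoolKinetics, times=None,
                          noise_fraction: float = 0.02,
                          seed=None, meta=None) -> IncubationSeries:
    """Simulate a cumulative CO2-C release series from known kinetics.

    The noiseless skeleton is the exact multi-exponential cumulative curve;
    noise is truncated Gaussian on the per-interval release increments
    (SD = ``noise_fraction`` x increment), then re-cumulated, so the noisy
    curve remains non-decreasing.
    """
    if noise_fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    if times is None:
        times = np.linspace(1.0, 365.0, 60)
    times = np.asarray(times, dtype=float)
    clean = cumulative_release(params, times)
    if noise_fraction == 0:
        cum = clean
    else:
        rng = np.random.default_rng(seed)
        inc = np.diff(np.concatenate([[0.0], clean]))
        noisy = inc + rng.normal(0.0, noise_fraction * inc)
        noisy = np.clip(noisy, 0.0, None)
        cum = np.cumsum(noisy)
    meta = dict(meta or {})
    meta.setdefault("duration", float(times[-1]))
    return IncubationSeries(times=times, cumulative=cum, meta=meta)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, coarse=6, amplitude=1.0):
    """Seeded smooth noise: coarse white noise bilinearly upsampled."""
    cr = max(coarse, 2)
    cc = max(int(coarse * shape[1] / shape[0]), 2)
    base = rng.normal(0.0, 1.0, (cr, cc))
    gi = np.linspace(0, cr - 1, shape[0])
    gj = np.linspace(0, cc - 1, shape[1])
    interp = RegularGridInterpolator((np.arange(cr), np.arange(cc)), base)
    pi, pj = np.meshgrid(gi, gj, indexing="ij")
    return amplitude * interp(np.column_stack([pi.ravel(), pj.ravel()])
                              ).reshape(shape)


# latitudinal tendency of each covariate's quantile field:
# +1 -> larger near the equator, -1 -> larger near the poles, 0 -> no gradient
_LAT_DIR = {"MAP": 1.0, "MAT": 1.0, "Sand": 0.4, "Clay": -0.3, "pH": -0.5,
            "SOC": -0.6, "MBC": 0.5, "Elev": 0.0, "Slope": 0.0, "NDVI": 0.8,
            "IncT": 0.0}


def gen_rasters(config: SyntheticConfig, shape=(30, 60), seed=None,
                lat_max=90.0, lat_min=-60.0) -> dict:
    """Covariate rasters: smooth latitudinal gradient + seeded spatial noise.

    Returns a dict of name -> :class:`Raster` for the eleven covariates plus
    ``pH_p5``/``pH_p95`` percentile layers (mean pH -/+ ``config.ph_spread``,
    clipped to the marginal range).  MAP tracks MAT, and Slope opposes Elev,
    mirroring the tabular dependence structure.
    """
    if shape[0] < 10 or shape[1] < 10:
        raise ValueError("grid must be at least 10 x 10")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    res = (lat_max - lat_min) / shape[0]
    nrows, ncols = shape
    lats = lat_max - res / 2 - res * np.arange(nrows)
    lat_w = np.cos(np.deg2rad(lats))[:, None] * np.ones((1, ncols))  # 0..1

    def make(u):
        return np.clip(u, 0.02, 0.98)

    u_fields = {}
    for name in COVARIATES:
        noise = _smooth_field(rng, shape, amplitude=0.18)
        u_fields[name] = make(0.5 + 0.38 * _LAT_DIR[name] * (lat_w - 0.5) * 2
                              + noise)
    # impose the two strong dependencies
    u_fields["MAP"] = make(0.8 * u_fields["MAT"]
                           + 0.2 * _smooth_field(rng, shape, amplitude=1.0) * 0.3
                           + 0.1)
    u_fields["Slope"] = make(1.0 - u_fields["Elev"]
                             + _smooth_field(rng, shape, amplitude=0.12))

    lon_min = -res * ncols / 2

    def raster(vals, name):
        return Raster(values=vals, lat_max=lat_max, lon_min=lon_min,
                      resolution=res, name=name)

    out = {}
    for name in COVARIATES:
        if name == "Clay":
            continue
        out[name] = raster(_MARGINALS[name][0](u_fields[name]), name)
    out["Clay"] = raster(_clay_from_u(u_fields["Clay"], out["Sand"].values),
                         "Clay")
    ph = out["pH"].values
    out["pH_p5"] = raster(np.clip(ph - config.ph_spread, 3.5, 9.5), "pH_p5")
    out["pH_p95"] = raster(np.clip(ph + config.ph_spread, 3.5, 9.5), "pH_p95")
    return out


def gen_world(config: SyntheticConfig, shape=(30, 60), seed=None):
    """Rasters plus a site table sampled from them (shared generator path).

    Site covariates are read off the rasters at randomly chosen cell centers,
    so raster sampling at site coordinates reproduces the table exactly.
    Returns (rasters, sites) where sites carries latitude/longitude columns.
    """
    seed = config.seed if seed is None else seed
    rasters = gen_rasters(config, shape=shape, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    ref = rasters["MAT"]
    nrows, ncols = ref.shape
    cells = rng.choice(nrows * ncols, size=min(config.n_sites, nrows * ncols),
                       replace=config.n_sites > nrows * ncols)
    i, j = np.unravel_index(cells, (nrows, ncols))
    sites = pd.DataFrame({"latitude": ref.lats[i], "longitude": ref.lons[j]})
    for name in COVARIATES:
        sites[name] = rasters[name].values[i, j]
    sites["Silt"] = 100.0 - sites["Sand"] - sites["Clay"]
    return rasters, sites


def true_parameter_raster(rasters: dict, config: SyntheticConfig,
                          target: str) -> Raster:
    """Noise-free true parameter field implied by the covariate rasters."""
    ref = rasters["MAT"]
    df = pd.DataFrame({name: rasters[name].values.ravel()
                       for name in COVARIATES})
    model, pool = target.split("_")
    cfg = replace(config, pool_model=model)
    params = true_parameter_map(df, cfg, seed=0, noise=False)
    return Raster(values=params[pool].to_numpy().reshape(ref.shape),
                  lat_max=ref.lat_max, lon_min=ref.lon_min,
                  resolution=ref.resolution, name=target)


# ---------------------------------------------------------------------------
# compiled-style kinetics table
# ---------------------------------------------------------------------------

_ECOSYSTEMS = ["forest", "grassland", "cropland", "shrubland", "wetland"]


def gen_kinetics_table(config: SyntheticConfig, seed=None,
                       m2_fraction: float = 0.5) -> pd.DataFrame:
    """A compiled-dataset-style table of fitted records with covariates.

    A fraction of records follow the two-pool map, the rest the three-pool
    map; parameters come from :func:`true_parameter_map`.  Fit-diagnostic
    columns carry plausible values (the table emulates a literature synthesis
    where the diagnostics were reported by the sources).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cov = gen_covariates(config, seed=seed)
    n = len(cov)
    n_m2 = int(round(n * m2_fraction))
    is_m2 = np.zeros(n, dtype=bool)
    is_m2[rng.permutation(n)[:n_m2]] = True

    p2 = true_parameter_map(cov, replace(config, pool_model="M2"),
                            seed=None if seed is None else seed + 10)
    p3 = true_parameter_map(cov, replace(config, pool_model="M3"),
                            seed=None if seed is None else seed + 11)

    df = cov.copy()
    df.insert(0, "record_id", [f"R{i:04d}" for i in range(n)])
    df.insert(1, "source_id", [f"S{i % 59:02d}" for i in range(n)])
    df.insert(2, "latitude", rng.uniform(-55, 70, n).round(4))
    df.insert(3, "longitude", rng.uniform(-180, 180, n).round(4))
    df["ecosystem"] = rng.choice(_ECOSYSTEMS, n)
    df["moisture"] = 60.0
    df["duration"] = rng.choice([120.0, 180.0, 365.0], n)
    df["measured"] = rng.choice(["CO2", "CO2+CH4", "13CO2"], n,
                                p=[0.9, 0.05, 0.05])
    df["model_type"] = np.where(is_m2, "M2", "M3")
    for c in ["f1", "f2", "f3", "k1", "k2", "k3"]:
        df[c] = np.nan
    for c in ["f1", "f2", "k1", "k2"]:
        df.loc[is_m2, c] = p2.loc[is_m2, c]
        df.loc[~is_m2, c] = p3.loc[~is_m2, c]
    df.loc[~is_m2, "f3"] = p3.loc[~is_m2, "f3"]
    df.loc[~is_m2, "k3"] = p3.loc[~is_m2, "k3"]
    df["r2_fit"] = np.round(1.0 - 10 ** rng.uniform(-3, -1, n), 4)
    df["rmse_fit"] = np.round(10 ** rng.uniform(-3, -1.5, n), 6)
    df["aic_fit"] = np.round(rng.uniform(-400, -100, n), 2)
    df["bic_fit"] = df["aic_fit"] + np.round(rng.uniform(0, 10, n), 2)
    return df
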