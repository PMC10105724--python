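"""Gridded prediction of decomposition kinetics parameters and uncertainty.

Rasters are plain lat/lon grids (WGS84 decimal degrees, rows ordered
north -> south, cell-center convention).  NaN marks nodata.  A trained
covariate->parameter model is applied cellwise; relative uncertainty

    ReUn = Width_90%CI / Mean

is propagated either from the 5%/95% percentile layers of an input (pH) or
from the spread of the individual trees of a random-forest model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "Raster", "ParameterGrid", "resample", "crop", "predict_grid",
    "input_uncertainty_ph", "structure_uncertainty", "latitudinal_profile",
]


@dataclass
class Raster:
    """A georeferenced lat/lon grid.

    ``values[0, 0]`` is the north-west cell; ``lat_max``/``lon_min`` are the
    outer edges of that cell and ``resolution`` the cell size in degrees.
    """

    values: np.ndarray
    lat_max: float
    lon_min: float
    resolution: float
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self):
        return self.values.shape

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.shape[0] * self.resolution

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.shape[1] * self.resolution

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, north to south."""
        r = self.resolution
        return self.lat_max - r / 2 - r * np.arange(self.shape[0])

    @property
    def lons(self) -> np.ndarray:
        r = self.resolution
        return self.lon_min + r / 2 + r * np.arange(self.shape[1])

    def sample(self, lat, lon):
        """Value at the cell whose center is nearest to (lat, lon).

        Points outside the raster extent return NaN.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((self.lat_max - lat) / self.resolution).astype(int)
        j = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        inside = (i >= 0) & (i < self.shape[0]) & (j >= 0) & (j < self.shape[1])
        out = np.full(np.broadcast(lat, lon).shape, np.nan)
        out[inside] = self.values[i[inside], j[inside]]
        return out if out.ndim else float(out)

    # -- text / NetCDF I/O ---------------------------------------------------

    def to_text(self, path):
        """Write the grid in the package's plain-text format."""
        with open(path, "w") as fh:
            fh.write(f"# somkin-raster v1 name={self.name or '-'}\n")
            fh.write(f"# lat_max={self.lat_max!r} lon_min={self.lon_min!r} "
                     f"resolution={self.resolution!r} "
                     f"nrows={self.shape[0]} ncols={self.shape[1]}\n")
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def from_text(cls, path) -> "Raster":
        with open(path) as fh:
            head = fh.readline()
            if not head.startswith("# somkin-raster"):
                raise ValueError(f"{path}: not a somkin raster file")
            name = head.split("name=", 1)[1].strip()
            name = "" if name == "-" else name
            meta = dict(tok.split("=") for tok in fh.readline()[1:].split())
            values = np.loadtxt(fh)
        values = values.reshape(int(meta["nrows"]), int(meta["ncols"]))
        return cls(values=values, lat_max=float(meta["lat_max"]),
                   lon_min=float(meta["lon_min"]),
                   resolution=float(meta["resolution"]), name=name)

    def to_netcdf(self, path):
        import xarray as xr

        da = xr.DataArray(self.values, coords={"lat": self.lats, "lon": self.lons},
                          dims=("lat", "lon"), name=self.name or "value")
        da.attrs["resolution"] = self.resolution
        da.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, var=None) -> "Raster":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            name = var or list(ds.data_vars)[0]
            da = ds[name]
            lats = da["lat"].values
            res = float(abs(lats[1] - lats[0]))
            vals = da.values
            if lats[0] < lats[-1]:  # stored south->north
                vals = vals[::-1]
                lats = lats[::-1]
            return cls(values=np.array(vals, dtype=float),
                       lat_max=float(lats[0] + res / 2),
                       lon_min=float(da["lon"].values[0] - res / 2),
                       resolution=res, name=str(name))


@dataclass
class ParameterGrid:
    """Predicted parameter field with optional uncertainty layers.

    ``lower``/``upper`` bound the 90% CI cellwise; ``reun`` is the relative
    uncertainty Width_90%CI / Mean.
    """

    mean: Raster
    lower: Raster | None = None
    upper: Raster | None = None
    reun: Raster | None = None
    parameter: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lower is not None and self.upper is not None:
            ok = np.isfinite(self.mean.values)
            lo, up = self.lower.values, self.upper.values
            m = self.mean.values
            bad = ok & np.isfinite(lo) & np.isfinite(up) & \
                ((lo > m + 1e-9) | (up < m - 1e-9))
            if bad.any():
                raise ValueError("lower <= mean <= upper violated cellwise")


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------

def resample(raster: Raster, resolution: float, method: str = "bilinear") -> Raster:
    """Resample to a new resolution over the same extent.

    Bilinear interpolation acts on cell centers; any contributing nodata cell
    propagates nodata.  Target centers outside the source center hull are
    clamped to the hull (edge cells extend outward by half a cell).
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError("method must be 'bilinear' or 'nearest'")
    if resolution / raster.resolution > 100:
        warnings.warn("resampling factor exceeds 100x")
    nrows = int(round((raster.lat_max - raster.lat_min) / resolution))
    ncols = int(round((raster.lon_max - raster.lon_min) / resolution))
    nrows, ncols = max(nrows, 1), max(ncols, 1)
    out = Raster(values=np.empty((nrows, ncols)), lat_max=raster.lat_max,
                 lon_min=raster.lon_min, resolution=resolution,
                 name=raster.name)
    src_lat = raster.lats[::-1]          # ascending for the interpolator
    src_vals = raster.values[::-1]
    interp = RegularGridInterpolator(
        (src_lat, raster.lons), src_vals,
        method="linear" if method == "bilinear" else "nearest",
        bounds_error=False, fill_value=np.nan)
    glat = np.clip(out.lats, src_lat[0], src_lat[-1])
    glon = np.clip(out.lons, raster.lons[0], raster.lons[-1])
    pts_lat, pts_lon = np.meshgrid(glat, glon, indexing="ij")
    out.values[:] = interp(np.column_stack([pts_lat.ravel(), pts_lon.ravel()])
                           ).reshape(nrows, ncols)
    return out


def crop(raster: Raster, lat_min=-60.0, lat_max=90.0,
         lon_min=-180.0, lon_max=180.0) -> Raster:
    """Keep cells whose centers fall inside the extent (default 60S–90N)."""
    keep_r = (raster.lats >= lat_min) & (raster.lats <= lat_max)
    keep_c = (raster.lons >= lon_min) & (raster.lons <= lon_max)
    if not keep_r.any() or not keep_c.any():
        raise ValueError("crop extent does not overlap raster")
    i = np.where(keep_r)[0]
    j = np.where(keep_c)[0]
    r = raster.resolution
    return Raster(values=raster.values[i[0]:i[-1] + 1, j[0]:j[-1] + 1].copy(),
                  lat_max=raster.lat_max - i[0] * r,
                  lon_min=raster.lon_min + j[0] * r,
                  resolution=r, name=raster.name)


def _check_coregistered(rasters: dict):
    items = list(rasters.values())
    ref = items[0]
    for r in items[1:]:
        if (r.shape != ref.shape or r.resolution != ref.resolution
                or abs(r.lat_max - ref.lat_max) > 1e-9
                or abs(r.lon_min - ref.lon_min) > 1e-9):
            raise ValueError("rasters are not co-registered")
    return ref


def _stack_features(model, rasters: dict):
    feats = list(model.selected_features_)
    missing = [f for f in feats if f not in rasters]
    if missing:
        raise ValueError(f"missing feature raster(s): {missing}")
    ref = _check_coregistered({f: rasters[f] for f in feats})
    X = np.column_stack([rasters[f].values.ravel() for f in feats])
    valid = np.isfinite(X).all(axis=1)
    return feats, ref, X, valid


def _predict_cells(model, X, valid):
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = model.predict(
            pd.DataFrame(X[valid], columns=list(model.selected_features_)))
    return out


def predict_grid(model, rasters: dict) -> ParameterGrid:
    """Apply a trained covariate model cellwise over co-registered rasters.

    ``rasters`` maps feature name -> :class:`Raster`.  Nodata in any input
    propagates to the output.  Predictions are identical to tabular
    ``model.predict`` on the stacked cell table.
    """
    feats, ref, X, valid = _stack_features(model, rasters)
    vals = _predict_cells(model, X, valid).reshape(ref.shape)
    mean = Raster(values=vals, lat_max=ref.lat_max, lon_min=ref.lon_min,
                  resolution=ref.resolution, name=getattr(model, "target_name_", ""))
    return ParameterGrid(mean=mean, parameter=mean.name,
                         provenance={"features": feats})


def _reun_from_bounds(mean_vals, lo_vals, hi_vals):
    width = np.abs(hi_vals - lo_vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        reun = width / mean_vals
    bad = ~(mean_vals > 0)
    reun[bad] = np.nan
    n_undef = int((bad & np.isfinite(width)).sum())
    return reun, n_undef


def input_uncertainty_ph(model, rasters: dict, ph5: Raster, ph95: Raster,
                         ph_name: str = "pH") -> ParameterGrid:
    """ReUn of the prediction due to pH input uncertainty.

    Width_90%CI is the difference between the predictions under the 95th- and
    5th-percentile pH layers; ReUn = |width| / mean prediction.  If pH is not
    among the model's features the prediction is invariant and ReUn = 0.
    """
    feats, ref, X, valid = _stack_features(model, rasters)
    mean_vals = _predict_cells(model, X, valid)
    if ph_name not in feats:
        reun = np.where(np.isfinite(mean_vals), 0.0, np.nan)
        lo = hi = mean_vals
    else:
        idx = feats.index(ph_name)
        Xlo, Xhi = X.copy(), X.copy()
        Xlo[:, idx] = ph5.values.ravel()
        Xhi[:, idx] = ph95.values.ravel()
        vlo = np.isfinite(Xlo).all(axis=1)
        vhi = np.isfinite(Xhi).all(axis=1)
        plo = _predict_cells(model, Xlo, vlo)
        phi = _predict_cells(model, Xhi, vhi)
        # the response need not be monotone in pH, so the percentile
        # predictions may sit on the same side of the central one; the CI
        # layers still bracket the mean while the width stays |p95 - p5|
        lo = np.minimum(np.minimum(plo, phi), mean_vals)
        hi = np.maximum(np.maximum(plo, phi), mean_vals)
        reun, n_undef = _reun_from_bounds(mean_vals, plo, phi)
        if n_undef:
            warnings.warn(f"{n_undef} cells with non-positive mean prediction "
                          "masked in ReUn")

    def _r(v, name):
        return Raster(values=v.reshape(ref.shape), lat_max=ref.lat_max,
                      lon_min=ref.lon_min, resolution=ref.resolution, name=name)

    return ParameterGrid(mean=_r(mean_vals, "mean"), lower=_r(lo, "lower"),
                         upper=_r(hi, "upper"), reun=_r(reun, "reun"),
                         provenance={"uncertainty": "input_pH"})


def structure_uncertainty(model, rasters: dict) -> ParameterGrid:
    """ReUn of an RF prediction from the spread of its individual trees.

    Width_90%CI is the 5th–95th empirical percentile range of the per-tree
    predictions; the denominator is the ensemble mean.
    """
    if not hasattr(model, "predict_per_tree"):
        raise TypeError("model does not expose per-tree predictions")
    feats, ref, X, valid = _stack_features(model, rasters)
    mean_vals = _predict_cells(model, X, valid)
    lo = np.full(X.shape[0], np.nan)
    hi = np.full(X.shape[0], np.nan)
    tree_mean = np.full(X.shape[0], np.nan)
    if valid.any():
        per_tree = model.predict_per_tree(
            pd.DataFrame(X[valid], columns=feats))  # (n_trees, n_valid)
        if per_tree.shape[0] < 10:
            warnings.warn("fewer than 10 trees: uncertainty quantiles unstable")
        lo[valid], hi[valid] = np.quantile(per_tree, [0.05, 0.95], axis=0)
        tree_mean[valid] = per_tree.mean(axis=0)
    reun, n_undef = _reun_from_bounds(tree_mean, lo, hi)
    # skewed per-tree distributions can put the ensemble mean outside the
    # empirical 5-95% band; the CI layers still bracket the mean while ReUn
    # keeps the quantile width
    lo = np.fmin(lo, tree_mean)
    hi = np.fmax(hi, tree_mean)
    if n_undef:
        warnings.warn(f"{n_undef} cells with non-positive mean masked in ReUn")

    def _r(v, name):
        return Raster(values=v.reshape(ref.shape), lat_max=ref.lat_max,
                      lon_min=ref.lon_min, resolution=ref.resolution, name=name)

    return ParameterGrid(mean=_r(tree_mean, "mean"), lower=_r(lo, "lower"),
                         upper=_r(hi, "upper"), reun=_r(reun, "reun"),
                         provenance={"uncertainty": "rf_structure"})


def latitudinal_profile(grid: ParameterGrid | Raster, band: float = 0.5,
                        area_weighted: bool = False) -> pd.DataFrame:
    """Per-latitude-band mean and 90% CI of a parameter grid.

    Bands of width ``band`` degrees partition the grid's latitude span from
    the north edge down; cells are aggregated across longitude.  Empty
    (all-nodata) bands appear with NaN entries.  ``area_weighted`` weights
    cells by cos(latitude) in the band mean.
    """
    raster = grid.mean if isinstance(grid, ParameterGrid) else grid
    if band <= 0:
        raise ValueError("band width must be positive")
    if not np.isfinite(raster.values).any():
        raise ValueError("grid is all nodata")
    span = raster.lat_max - raster.lat_min
    n_bands = int(np.ceil(span / band - 1e-9))
    lats = raster.lats
    rows = []
    for b in range(n_bands):
        top = raster.lat_max - b * band
        bot = top - band
        sel = (lats <= top + 1e-12) & (lats > bot + 1e-12)
        vals = raster.values[sel].ravel()
        w = None
        if area_weighted:
            w = np.repeat(np.cos(np.deg2rad(lats[sel])), raster.shape[1])
        ok = np.isfinite(vals)
        if ok.any():
            if area_weighted:
                mean = float(np.average(vals[ok], weights=w[ok]))
            else:
                mean = float(vals[ok].mean())
            lo, hi = np.quantile(vals[ok], [0.05, 0.95])
        else:
            mean = lo = hi = np.nan
        rows.append({"lat_center": top - band / 2, "mean": mean,
                     "ci90_low": float(lo), "ci90_high": float(hi),
                     "n_cells": int(ok.sum())})
    return pd.DataFrame(rows)
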