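"""Raster operations, gridded prediction and uncertainty propagation."""

import numpy as np
import pandas as pd
import pytest

from somkin import ml, mapping
from somkin.mapping import (ParameterGrid, Raster, crop, input_uncertainty_ph,
                            latitudinal_profile, predict_grid, resample,
                            structure_uncertainty)
from somkin.synthetic import SyntheticConfig, gen_world


@pytest.fixture(scope="module")
def world(small_config):
    cfg = SyntheticConfig(n_sites=250)
    return gen_world(cfg, shape=(24, 48), seed=11)


@pytest.fixture(scope="module")
def rf_on_world(world, small_config):
    from somkin.synthetic import true_parameter_map
    rasters, sites = world
    y = true_parameter_map(sites[ml.COVARIATES], small_config,
                           seed=13)["k3"].to_numpy()
    return ml.train_model(sites[ml.COVARIATES], y, method="rf",
                          target_name="M3_k3", rfe=False, seed=0, cv_folds=3,
                          cv_repeats=1, grid={"max_features": [4]})


class TestRasterBasics:
    def test_text_round_trip(self, tmp_path):
        r = Raster(values=np.arange(12.0).reshape(3, 4), lat_max=90,
                   lon_min=-180, resolution=30, name="x")
        r.values[1, 2] = np.nan
        r.to_text(tmp_path / "r.txt")
        r2 = Raster.from_text(tmp_path / "r.txt")
        np.testing.assert_array_equal(np.isnan(r2.values), np.isnan(r.values))
        np.testing.assert_allclose(r2.values[0], r.values[0])
        assert (r2.lat_max, r2.lon_min, r2.resolution) == (90, -180, 30)

    def test_netcdf_round_trip(self, tmp_path):
        r = Raster(values=np.arange(6.0).reshape(2, 3), lat_max=60,
                   lon_min=0, resolution=20, name="pH")
        r.to_netcdf(tmp_path / "r.nc")
        r2 = Raster.from_netcdf(tmp_path / "r.nc")
        np.testing.assert_allclose(r2.values, r.values)
        assert r2.resolution == 20

    def test_sample_nearest_cell(self):
        r = Raster(values=np.array([[1.0, 2.0], [3.0, 4.0]]), lat_max=2,
                   lon_min=0, resolution=1)
        assert r.sample(1.5, 0.5) == 1.0
        assert r.sample(0.5, 1.5) == 4.0
        assert np.isnan(r.sample(5.0, 0.5))


class TestResample:
    def test_constant_preserved(self):
        r = Raster(values=np.full((10, 10), 3.3), lat_max=50, lon_min=0,
                   resolution=1)
        out = resample(r, 2.5)
        np.testing.assert_allclose(out.values, 3.3)

    def test_bilinear_midpoint(self):
        r = Raster(values=np.array([[1.0, 2.0], [3.0, 4.0]]), lat_max=2,
                   lon_min=0, resolution=1)
        out = resample(r, 2.0)  # single cell centered in the middle
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_linear_gradient_exact(self):
        lon = np.arange(20)
        r = Raster(values=np.tile(lon, (10, 1)).astype(float), lat_max=10,
                   lon_min=0, resolution=1)
        out = resample(r, 0.5)
        # gradient in lon: value = column center position - 0.5
        expected = out.lons - 0.5
        interior = (out.lons > 0.5) & (out.lons < 19.5)
        np.testing.assert_allclose(out.values[3][interior],
                                   expected[interior], atol=1e-9)

    def test_nodata_propagates(self):
        v = np.ones((4, 4))
        v[1, 1] = np.nan
        r = Raster(values=v, lat_max=4, lon_min=0, resolution=1)
        out = resample(r, 0.5)
        assert np.isnan(out.values).any()

    def test_bad_method(self):
        r = Raster(values=np.ones((2, 2)), lat_max=2, lon_min=0, resolution=1)
        with pytest.raises(ValueError):
            resample(r, 1.0, method="cubic")


class TestCrop:
    def test_identity(self):
        r = Raster(values=np.random.default_rng(0).normal(size=(6, 8)),
                   lat_max=90, lon_min=-180, resolution=30)
        out = crop(r, r.lat_min, r.lat_max, r.lon_min, r.lon_max)
        np.testing.assert_array_equal(out.values, r.values)

    def test_southern_rows_removed_values_untouched(self):
        r = Raster(values=np.arange(36.0).reshape(18, 2), lat_max=90,
                   lon_min=0, resolution=10)
        out = crop(r, lat_min=-60, lat_max=90)
        assert out.shape[0] == int(np.ceil(150 / 10))
        np.testing.assert_array_equal(out.values, r.values[:15])

    def test_empty_intersection(self):
        r = Raster(values=np.ones((3, 3)), lat_max=90, lon_min=0, resolution=1)
        with pytest.raises(ValueError):
            crop(r, lat_min=-90, lat_max=-80)


class TestPredictGrid:
    def test_equals_tabular_prediction(self, world, rf_on_world):
        rasters, _ = world
        grid = predict_grid(rf_on_world, rasters)
        X = pd.DataFrame({f: rasters[f].values.ravel()
                          for f in rf_on_world.selected_features_})
        np.testing.assert_allclose(grid.mean.values.ravel(),
                                   rf_on_world.predict(X), rtol=1e-12)

    def test_constant_rasters_give_point_prediction(self, rf_on_world):
        const = {f: Raster(values=np.full((10, 10), v), lat_max=50, lon_min=0,
                           resolution=5, name=f)
                 for f, v in zip(rf_on_world.selected_features_,
                                 [1000, 10, 40, 20, 6.5, 20, 100, 500, 5,
                                  0.5, 25])}
        grid = predict_grid(rf_on_world, const)
        assert np.ptp(grid.mean.values) == 0

    def test_nodata_propagates(self, world, rf_on_world):
        rasters, _ = world
        rasters = {k: Raster(values=v.values.copy(), lat_max=v.lat_max,
                             lon_min=v.lon_min, resolution=v.resolution,
                             name=v.name) for k, v in rasters.items()}
        rasters["pH"].values[0, 0] = np.nan
        grid = predict_grid(rf_on_world, rasters)
        assert np.isnan(grid.mean.values[0, 0])

    def test_missing_raster_named(self, world, rf_on_world):
        rasters, _ = world
        sub = {k: v for k, v in rasters.items() if k != "pH"}
        with pytest.raises(ValueError, match="pH"):
            predict_grid(rf_on_world, sub)


class _ScaledModel:
    """Wraps a trained model, scaling every prediction by c."""

    def __init__(self, inner, c):
        self.inner, self.c = inner, c
        self.selected_features_ = inner.selected_features_

    def predict(self, X):
        return self.c * self.inner.predict(X)

    def predict_per_tree(self, X):
        return self.c * self.inner.predict_per_tree(X)


class TestUncertainty:
    def test_collapsed_percentiles_zero_reun(self, world, rf_on_world):
        rasters, _ = world
        g = input_uncertainty_ph(rf_on_world, rasters, rasters["pH"],
                                 rasters["pH"])
        assert np.nanmax(g.reun.values) == 0.0

    def test_model_without_ph_zero_reun(self, world):
        from somkin.synthetic import true_parameter_map
        rasters, sites = world
        cfg = SyntheticConfig(n_sites=250)
        y = true_parameter_map(sites[ml.COVARIATES], cfg, seed=13)["k3"]
        m = ml.train_model(sites[["MAP", "MAT", "Sand"]], y.to_numpy(),
                           method="mlr", target_name="M3_k3", rfe=False,
                           seed=0, cv_folds=3, cv_repeats=1,
                           target_transform="log10")
        g = input_uncertainty_ph(m, rasters, rasters["pH_p5"],
                                 rasters["pH_p95"])
        assert np.nanmax(g.reun.values) == 0.0

    def test_reun_hand_arithmetic(self):
        lo, hi = np.array([[1.0]]), np.array([[2.0]])
        mean = np.array([[2.0]])
        reun, n = mapping._reun_from_bounds(mean, lo, hi)
        assert reun[0, 0] == pytest.approx(0.5) and n == 0

    def test_reun_scale_invariance(self, world, rf_on_world):
        rasters, _ = world
        base = input_uncertainty_ph(rf_on_world, rasters, rasters["pH_p5"],
                                    rasters["pH_p95"])
        scaled = input_uncertainty_ph(_ScaledModel(rf_on_world, 3.0), rasters,
                                      rasters["pH_p5"], rasters["pH_p95"])
        np.testing.assert_allclose(scaled.reun.values, base.reun.values,
                                   rtol=1e-10)

    def test_structure_quantiles_match_sorted_oracle(self, world, rf_on_world):
        rasters, _ = world
        g = structure_uncertainty(rf_on_world, rasters)
        X = pd.DataFrame({f: rasters[f].values.ravel()
                          for f in rf_on_world.selected_features_})
        per_tree = rf_on_world.predict_per_tree(X)  # (trees, cells)
        cell = 7
        col = np.sort(per_tree[:, cell])
        lo = np.quantile(col, 0.05)
        hi = np.quantile(col, 0.95)
        mean = per_tree[:, cell].mean()
        assert g.reun.values.ravel()[cell] == pytest.approx(
            (hi - lo) / mean, rel=1e-9)

    def test_structure_scale_invariance(self, world, rf_on_world):
        rasters, _ = world
        base = structure_uncertainty(rf_on_world, rasters)
        scaled = structure_uncertainty(_ScaledModel(rf_on_world, 2.5), rasters)
        np.testing.assert_allclose(scaled.reun.values, base.reun.values,
                                   rtol=1e-10)


class TestLatitudinalProfile:
    def test_constant_grid(self):
        r = Raster(values=np.full((20, 10), 4.0), lat_max=90, lon_min=0,
                   resolution=5)
        prof = latitudinal_profile(r, band=10.0)
        assert len(prof) == 10
        np.testing.assert_allclose(prof["mean"], 4.0)
        np.testing.assert_allclose(prof["ci90_high"] - prof["ci90_low"], 0.0)

    def test_linear_in_latitude(self):
        lats = 90 - 2.5 - 5.0 * np.arange(30)
        r = Raster(values=np.tile(lats[:, None], (1, 6)), lat_max=90,
                   lon_min=0, resolution=5)
        prof = latitudinal_profile(r, band=5.0)
        np.testing.assert_allclose(prof["mean"], prof["lat_center"], atol=2.5)

    def test_longitude_shuffle_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(12, 24))
        r = Raster(values=v, lat_max=60, lon_min=0, resolution=5)
        shuf = Raster(values=np.take(v, rng.permutation(24), axis=1),
                      lat_max=60, lon_min=0, resolution=5)
        a = latitudinal_profile(r, band=5.0)
        b = latitudinal_profile(shuf, band=5.0)
        np.testing.assert_allclose(a["mean"], b["mean"])

    def test_band_count_geometry(self):
        r = Raster(values=np.ones((30, 4)), lat_max=90, lon_min=0,
                   resolution=5)   # span 150 degrees
        assert len(latitudinal_profile(r, band=0.5)) == 300

    def test_all_nodata_error(self):
        r = Raster(values=np.full((10, 10), np.nan), lat_max=50, lon_min=0,
                   resolution=1)
        with pytest.raises(ValueError):
            latitudinal_profile(r, band=5.0)
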