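import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from shapely.geometry import box

import geomort as gm
from geomort.rasters import CovariateStack, GridGeometry, Raster

from conftest import make_samples


def flat_geom(nrows=4, ncols=4):
    return GridGeometry(nrows=nrows, ncols=ncols, xllcorner=0.0,
                        yllcorner=0.0, cellsize=1.0)


def no_covariate_spec(geom, spatial=False):
    return gm.ModelSpec(covariates=[], geometry=geom, n_surveys=1,
                        spatial=spatial)


def empty_design(n=1):
    d = gm.DesignMatrix(X=np.zeros((n, 0)), names=[],
                        cluster_ids=np.arange(n))
    return gm.standardize(d)


class TestPredictSurface:
    def test_degenerate_posterior_gives_constant_surface(self):
        geom = flat_geom()
        stack = CovariateStack({"dummy": Raster(geom, np.zeros((4, 4)))})
        samples = make_samples(alpha=np.full((10, 1), -2.0))
        surf = gm.predict_surface(samples, stack, no_covariate_spec(geom),
                                  empty_design())
        np.testing.assert_allclose(surf.mean, expit(-2.0), atol=1e-12)
        np.testing.assert_allclose(surf.lower, surf.upper, atol=1e-12)

    def test_training_mean_cell_recovers_intercept(self):
        # where the covariate equals its training mean the standardized
        # value is 0, so p = inverse-logit(alpha) exactly
        geom = flat_geom(1, 3)
        vals = np.array([[2.0, 5.0, 8.0]])
        stack = CovariateStack({"x": Raster(geom, vals)})
        train = gm.DesignMatrix(X=np.array([[2.0], [8.0]]), names=["x"],
                                cluster_ids=np.arange(2))
        train = gm.standardize(train)  # mean 5, sd 3
        spec = gm.ModelSpec(covariates=["x"], geometry=geom, n_surveys=1,
                            spatial=False)
        samples = make_samples(alpha=np.full((20, 1), -1.3),
                               beta=np.full((20, 1), 0.7),
                               covariates=["x"])
        surf = gm.predict_surface(samples, stack, spec, train)
        assert surf.mean[0, 1] == pytest.approx(float(expit(-1.3)), abs=1e-12)
        assert surf.mean[0, 0] < surf.mean[0, 1] < surf.mean[0, 2]

    def test_two_draw_average_hand_computed(self):
        geom = flat_geom(1, 1)
        stack = CovariateStack({"d": Raster(geom, np.zeros((1, 1)))})
        samples = make_samples(alpha=np.array([[0.0], [np.log(3.0)]]))
        surf = gm.predict_surface(samples, stack, no_covariate_spec(geom),
                                  empty_design())
        assert surf.mean[0, 0] == pytest.approx((0.5 + 0.75) / 2, abs=1e-12)

    def test_quantile_ordering_and_bounds(self, small_fit):
        samples, spec, design, data = small_fit
        geom = spec.geometry
        rng = np.random.default_rng(0)
        rasters = {
            name: Raster(geom, rng.normal(size=(geom.nrows, geom.ncols)))
            for name in design.names}
        surf = gm.predict_surface(samples, CovariateStack(rasters), spec,
                                  design)
        assert np.all((surf.mean >= 0) & (surf.mean <= 1))
        assert np.all(surf.lower <= surf.mean + 1e-12)
        assert np.all(surf.mean <= surf.upper + 1e-12)


class TestAggregateRegions:
    def surface(self, geom, p, year=2000):
        p = np.broadcast_to(p, (geom.nrows, geom.ncols)).astype(float)
        return gm.PredictedSurface(geometry=geom, mean=p, lower=p * 0.9,
                                   upper=np.minimum(1.0, p * 1.1),
                                   survey_year=year)

    def test_uniform_surface_gives_uniform_rates(self):
        geom = flat_geom(10, 10)
        regions = gm.make_regions(geom, nx=2, ny=2)
        rates = gm.aggregate_regions(self.surface(geom, 0.121), regions)
        np.testing.assert_allclose(rates[2000], 121.0, atol=1e-9)
        assert rates.attrs["unassigned_cells"] == 0

    def test_identity_partition_equals_national(self):
        geom = flat_geom(6, 5)
        rng = np.random.default_rng(1)
        surf = self.surface(geom, rng.uniform(0.02, 0.2, size=(6, 5)))
        whole = [("all", box(0, 0, 5, 6))]
        rates = gm.aggregate_regions(surf, whole)
        assert rates.loc["all", 2000] == pytest.approx(
            rates.loc["national", 2000], abs=1e-12)

    def test_two_equal_regions_average(self):
        geom = flat_geom(2, 2)
        p = np.array([[0.02, 0.02], [0.10, 0.10]])
        surf = self.surface(geom, p)
        regions = [("top", box(0, 1, 2, 2)), ("bottom", box(0, 0, 2, 1))]
        rates = gm.aggregate_regions(surf, regions)
        assert rates.loc["top", 2000] == pytest.approx(20.0)
        assert rates.loc["bottom", 2000] == pytest.approx(100.0)
        assert rates.loc["national", 2000] == pytest.approx(60.0)

    def test_national_is_weighted_mean_of_regions(self):
        geom = flat_geom(8, 8)
        rng = np.random.default_rng(2)
        surf = self.surface(geom, rng.uniform(0.01, 0.3, size=(8, 8)))
        regions = gm.make_regions(geom, nx=2, ny=2)
        w = Raster(geom, rng.uniform(0.5, 10.0, size=(8, 8)))
        rates = gm.aggregate_regions(surf, regions, weights=w)
        # recombine regional rates with regional weight totals
        assign, _ = gm.prediction._assign_cells(geom, regions)
        wsum = np.array([w.flat()[assign == k].sum() for k in range(4)])
        recombined = np.average(
            rates[2000].to_numpy()[:4], weights=wsum)
        assert rates.loc["national", 2000] == pytest.approx(recombined,
                                                            abs=1e-9)

    def test_population_weighting_shifts_rates(self):
        geom = flat_geom(2, 1)
        p = np.array([[0.05], [0.15]])
        surf = self.surface(geom, p)
        regions = [("all", box(0, 0, 1, 2))]
        w = Raster(geom, np.array([[3.0], [1.0]]))
        rates = gm.aggregate_regions(surf, regions, weights=w)
        assert rates.loc["national", 2000] == pytest.approx(
            1000 * (0.05 * 3 + 0.15) / 4)

    def test_uncovered_cells_counted(self):
        geom = flat_geom(4, 4)
        surf = self.surface(geom, 0.1)
        half = [("left", box(0, 0, 2, 4))]
        rates = gm.aggregate_regions(surf, half)
        assert rates.attrs["unassigned_cells"] == 8


class TestTrendTable:
    def national(self, values, years=(2000, 2005, 2011, 2016, 2019)):
        return pd.DataFrame({y: [v] for y, v in zip(years, values)},
                            index=["national"])

    def test_observed_national_trajectory(self):
        # the canonical declining series: fast early decline, flat finish
        rates = self.national([121.0, 87.0, 73.0, 60.0, 59.0])
        t = gm.trend_table(rates).loc["national"]
        assert t["change_first_last"] == pytest.approx(-62.0)
        assert t["monotone_decreasing"]
        assert t["stagnation"]  # |60 -> 59| is under 5% of 60
        assert t["pct_change_first_last"] == pytest.approx(-51.24, abs=0.01)

    def test_constant_series(self):
        t = gm.trend_table(self.national([80, 80, 80], years=(1, 2, 3)))
        row = t.loc["national"]
        assert row["change_first_last"] == 0
        assert row["stagnation"] and row["monotone_decreasing"]

    def test_rising_series(self):
        t = gm.trend_table(self.national([40, 80], years=(1, 2)))
        row = t.loc["national"]
        assert row["pct_change_first_last"] == pytest.approx(100.0)
        assert not row["monotone_decreasing"]
        assert not row["stagnation"]

    def test_single_survey_rejected(self):
        with pytest.raises(ValueError):
            gm.trend_table(self.national([50], years=(2000,)))


class TestRenderMaps:
    def test_tif_round_trip_and_png(self, tmp_path):
        import tifffile

        geom = flat_geom(10, 10)
        rng = np.random.default_rng(3)
        p = rng.uniform(0.02, 0.3, size=(10, 10))
        p[0, 0] = np.nan  # NODATA cell
        surf = gm.PredictedSurface(geometry=geom, mean=p, lower=p * 0.8,
                                   upper=np.minimum(1, p * 1.2),
                                   survey_year=2019)
        paths = gm.render_maps(surf, tmp_path / "map")
        bands = tifffile.imread(paths["tif"])
        assert bands.shape == (3, 10, 10)
        np.testing.assert_allclose(bands[0], p.astype(np.float32),
                                   rtol=1e-6, equal_nan=True)
        assert np.isnan(bands[0, 0, 0])
        assert paths["png"].stat().st_size > 0
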