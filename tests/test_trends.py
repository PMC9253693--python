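import numpy as np
import pandas as pd
import pytest

from marshagb.errors import AlignmentError, EmptyRegionError
from marshagb.raster import AnnualStack, Raster, RasterGrid
from marshagb.trends import (
    PERIOD_ROWS,
    TABLE_COLUMNS,
    correlation_table,
    latitude_split,
    pearson_p,
    pearson_r,
    pixelwise_map,
    regional_series,
    slope_significance,
    theta_slope,
)


def _ols_slope(y):
    """Independent normal-equations OLS slope oracle."""
    i = np.arange(1, len(y) + 1, dtype=float)
    X = np.column_stack([np.ones_like(i), i])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1]


class TestThetaSlope:
    def test_constant_series_zero(self):
        assert theta_slope(np.full(21, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        i = np.arange(1, 22)
        assert theta_slope(2.0 * i + 7.0) == pytest.approx(2.0)

    def test_matches_ols_oracle_on_random_series(self, rng):
        ys = rng.normal(size=(1000, 21))
        slopes = theta_slope(ys, axis=-1)
        for k in range(1000):
            assert abs(slopes[k] - _ols_slope(ys[k])) < 1e-10

    def test_missing_values_yield_nan(self):
        y = np.arange(21, dtype=float)
        y[5] = np.nan
        assert np.isnan(theta_slope(y))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            theta_slope(np.array([1.0, 2.0]))


class TestSlopeSignificance:
    def test_strong_trend_tiny_noise(self, rng):
        y = 5.0 * np.arange(21) + rng.normal(0, 1e-3, 21)
        assert slope_significance(y) < 1e-6

    def test_type_one_error_calibrated(self, rng):
        ys = rng.normal(size=(1000, 21))
        p = slope_significance(ys, axis=-1)
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_null_p_values_approximately_uniform(self, rng):
        # near-zero slope in noise: p should look uniform across replicates
        ys = 10.0 + 0.0001 * np.arange(21) + rng.normal(0, 1.0, (2000, 21))
        p = slope_significance(ys, axis=-1)
        # compare deciles of the p distribution with uniform
        hist, _ = np.histogram(p, bins=10, range=(0, 1))
        assert np.all(hist > 120) and np.all(hist < 280)

    def test_zero_residual_variance_gives_zero(self):
        assert slope_significance(2.0 * np.arange(1, 22)) == 0.0


class TestPearson:
    def test_identity_series(self, rng):
        x = rng.normal(size=21)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negative_affine(self, rng):
        x = rng.normal(size=21)
        assert pearson_r(x, -3.0 * x + 5.0) == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        for _ in range(200):
            x, y = rng.normal(size=(2, 21))
            direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert abs(pearson_r(x, y) - direct) < 1e-12

    def test_affine_invariance_and_antisymmetry(self, rng):
        x, y = rng.normal(size=(2, 21))
        r = pearson_r(x, y)
        assert pearson_r(2.5 * x + 1.0, y) == pytest.approx(r, abs=1e-12)
        assert pearson_r(x, 0.3 * y - 7.0) == pytest.approx(r, abs=1e-12)
        assert pearson_r(-x, y) == pytest.approx(-r, abs=1e-12)

    def test_zero_variance_signals_missing(self):
        assert np.isnan(pearson_r(np.full(21, 2.0), np.arange(21.0)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.arange(5.0), np.arange(6.0))

    def test_p_value_matches_scipy(self, rng):
        from scipy import stats

        x, y = rng.normal(size=(2, 21))
        r = pearson_r(x, y)
        expected = stats.pearsonr(x, y).pvalue
        assert pearson_p(r, 21) == pytest.approx(expected, rel=1e-9)


def _random_stack(grid, years, rng):
    return AnnualStack(grid, years, rng.normal(size=(len(years),) + grid.shape))


class TestPixelwiseMap:
    grid = RasterGrid(20, 20, 0, 0, 250.0)
    years = tuple(range(2000, 2021))

    def test_correlation_with_itself_is_one(self, rng):
        st = _random_stack(self.grid, self.years, rng)
        mask = Raster.full(self.grid, 1.0)
        out = pixelwise_map(st, st, mask, "correlation")
        np.testing.assert_allclose(out.values.values, 1.0, atol=1e-12)
        assert np.all(out.p_values.values < 1e-10)

    def test_matches_scalar_double_loop(self, rng):
        agb = _random_stack(self.grid, self.years, rng)
        cov = _random_stack(self.grid, self.years, rng)
        mask_arr = rng.random(self.grid.shape) > 0.3
        mask = Raster.from_bool(self.grid, mask_arr)
        corr = pixelwise_map(agb, cov, mask, "correlation")
        trend = pixelwise_map(agb, None, mask, "trend")
        for i in range(self.grid.nrows):
            for j in range(self.grid.ncols):
                if not mask_arr[i, j]:
                    assert np.isnan(corr.values.values[i, j])
                    assert np.isnan(trend.values.values[i, j])
                else:
                    yv = agb.values[:, i, j]
                    assert corr.values.values[i, j] == pytest.approx(
                        pearson_r(cov.values[:, i, j], yv), abs=1e-12)
                    assert trend.values.values[i, j] == pytest.approx(
                        theta_slope(yv), abs=1e-12)

    def test_pixels_with_missing_years_are_skipped(self, rng):
        vals = rng.normal(size=(len(self.years),) + self.grid.shape)
        vals[3, 5, 5] = np.nan
        st = AnnualStack(self.grid, self.years, vals)
        out = pixelwise_map(st, None, Raster.full(self.grid, 1.0), "trend")
        assert np.isnan(out.values.values[5, 5])
        assert np.isfinite(out.values.values[0, 0])

    def test_year_mismatch_raises_alignment_error(self, rng):
        agb = _random_stack(self.grid, self.years, rng)
        cov = _random_stack(self.grid, tuple(range(2001, 2022)), rng)
        with pytest.raises(AlignmentError):
            pixelwise_map(agb, cov, Raster.full(self.grid, 1.0), "correlation")


class TestRegionalSeries:
    grid = RasterGrid(8, 8, 0, 0, 250.0)
    years = (2000, 2001, 2002, 2003)

    def test_uniform_stack(self):
        st = AnnualStack(self.grid, self.years,
                         np.full((4,) + self.grid.shape, 7.5))
        s = regional_series(st, Raster.full(self.grid, 1.0))
        assert list(s.index) == list(self.years)
        np.testing.assert_allclose(s.to_numpy(), 7.5)

    def test_single_masked_pixel_returns_its_series(self, rng):
        vals = rng.normal(size=(4,) + self.grid.shape)
        st = AnnualStack(self.grid, self.years, vals)
        m = np.zeros(self.grid.shape)
        m[2, 3] = 1
        s = regional_series(st, Raster(self.grid, m))
        np.testing.assert_allclose(s.to_numpy(), vals[:, 2, 3])

    def test_matches_loop_mean(self, rng):
        vals = rng.normal(size=(4,) + self.grid.shape)
        vals[0, 0, 0] = np.nan
        st = AnnualStack(self.grid, self.years, vals)
        m = rng.random(self.grid.shape) > 0.4
        s = regional_series(st, Raster.from_bool(self.grid, m))
        for k in range(4):
            sel = vals[k][m]
            assert s.iloc[k] == pytest.approx(np.mean(sel[~np.isnan(sel)]))


class TestCorrelationTable:
    years = list(range(2000, 2021))

    def _climate(self, rng):
        out = {}
        for var in TABLE_COLUMNS:
            for period in ["annual"] + list(range(1, 13)):
                out[(var, period)] = pd.Series(rng.normal(size=21), index=self.years)
        return out

    def test_shape_and_bounds(self, rng):
        agb = pd.Series(rng.normal(size=21), index=self.years)
        tbl = correlation_table(agb, self._climate(rng))
        assert tbl.r.shape == (13, 4)
        assert list(tbl.r.index) == list(PERIOD_ROWS)
        finite = tbl.r.to_numpy()[np.isfinite(tbl.r.to_numpy())]
        assert np.all(np.abs(finite) <= 1.0)

    def test_agb_equal_to_july_tmean_gives_unit_flagged_cell(self, rng):
        clim = self._climate(rng)
        agb = clim[("tmean", 7)].copy()
        tbl = correlation_table(agb, clim)
        assert tbl.r.loc["July", "tmean"] == pytest.approx(1.0)
        assert tbl.stars().loc["July", "tmean"] == "**"

    def test_white_noise_cells_rarely_flagged(self, rng):
        # under independence each cell is flagged at ~5%; across replicates
        # the per-cell flag frequency must stay below 10%
        flags = np.zeros((13, 4))
        reps = 300
        for _ in range(reps):
            agb = pd.Series(rng.normal(size=21), index=self.years)
            tbl = correlation_table(agb, self._climate(rng))
            flags += (tbl.p.to_numpy() < 0.05).astype(float)
        assert np.all(flags / reps < 0.10)

    def test_alignment_error_on_length_mismatch(self, rng):
        agb = pd.Series(rng.normal(size=21), index=self.years)
        clim = self._climate(rng)
        clim[("precip", 1)] = pd.Series(rng.normal(size=20), index=self.years[:-1])
        with pytest.raises(AlignmentError):
            correlation_table(agb, clim)

    def test_csv_layout(self, rng, tmp_path):
        agb = pd.Series(rng.normal(size=21), index=self.years)
        tbl = correlation_table(agb, self._climate(rng))
        path = tmp_path / "table.csv"
        tbl.to_csv(path)
        back = pd.read_csv(path, index_col="period")
        assert list(back.index) == list(PERIOD_ROWS)
        assert "precip_sig" in back.columns


class TestLatitudeSplit:
    grid = RasterGrid(10, 10, 0, 0, 250.0)
    years = tuple(range(2000, 2021))

    def _stacks(self, rng):
        agb = _random_stack(self.grid, self.years, rng)
        clim = {("tmean", 7): _random_stack(self.grid, self.years, rng)}
        return agb, clim

    def test_all_pixels_north_raises_for_south(self, rng):
        agb, clim = self._stacks(rng)
        lat = self.grid.latitude_raster(48.5)  # whole grid north of 47
        with pytest.raises(EmptyRegionError) as exc:
            latitude_split(agb, clim, Raster.full(self.grid, 1.0), lat, 47.0)
        assert exc.value.region == "south"

    def test_homogeneous_scene_gives_similar_regions(self, rng):
        agb = _random_stack(self.grid, self.years, rng)
        shared = rng.normal(size=len(self.years))
        # same signal everywhere plus noise: both regions should agree
        vals = shared[:, None, None] + 0.1 * rng.normal(
            size=(len(self.years),) + self.grid.shape)
        agb = AnnualStack(self.grid, self.years, vals)
        clim = {("tmean", 7): AnnualStack(
            self.grid, self.years,
            np.broadcast_to(shared[:, None, None],
                            (len(self.years),) + self.grid.shape).copy())}
        lat = self.grid.latitude_raster(47.0 + 5 * 250.0 / 111320.0)
        out = latitude_split(agb, clim, Raster.full(self.grid, 1.0), lat, 47.0)
        r_s = out["south"].r.loc["July", "tmean"]
        r_n = out["north"].r.loc["July", "tmean"]
        assert r_s == pytest.approx(r_n, abs=0.05)
        assert r_s > 0.9
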