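import numpy as np
import pytest

from marshagb.agb import (
    CalibratedModel,
    fit_candidates,
    predict_raster,
    regional_summary,
    select_best,
    site_carbon_density,
    validate,
    write_sites_csv,
    read_sites_csv,
    SampleSite,
)
from marshagb.errors import EmptyRegionError, ModelSelectionError
from marshagb.raster import Raster, RasterGrid

PUB_A, PUB_B = 643.57, 4.2474


class TestSiteCarbonDensity:
    @pytest.mark.parametrize(
        "quadrats,expected",
        [((100, 100, 100), 45.0), ((0, 0, 0), 0.0), ((80, 100, 120), 45.0)],
    )
    def test_mean_times_carbon_fraction(self, quadrats, expected):
        assert site_carbon_density(quadrats) == pytest.approx(expected)

    def test_negative_quadrat_rejected(self):
        with pytest.raises(ValueError):
            site_carbon_density((10, -1, 10))

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            site_carbon_density((10, 10))


class TestFitCandidates:
    def test_noise_free_power_data_recovers_published_parameters(self, rng):
        x = rng.uniform(0.4, 0.95, 16)
        pairs = np.column_stack([x, PUB_A * x**PUB_B])
        models = {m.form: m for m in fit_candidates(pairs)}
        p = models["power"]
        assert p.a == pytest.approx(PUB_A, rel=1e-6)
        assert p.b == pytest.approx(PUB_B, rel=1e-6)
        assert p.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_line_gives_linear_r2_one(self):
        x = np.linspace(0.1, 1.0, 10)
        models = {m.form: m for m in fit_candidates(np.column_stack([x, 2 * x]))}
        assert models["linear"].r_squared == pytest.approx(1.0, abs=1e-12)
        assert models["linear"].a == pytest.approx(2.0)
        assert models["linear"].b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_power_fit_beats_dense_grid_search(self):
        """The NLS optimum must be at least as good as a dense grid search."""
        rng = np.random.default_rng(99)
        x = rng.uniform(0.5, 0.95, 16)
        y = PUB_A * x**PUB_B * np.exp(0.15 * rng.standard_normal(16))
        models = {m.form: m for m in fit_candidates(np.column_stack([x, y]))}
        p = models["power"]
        fit_ss = np.sum((y - p.a * x**p.b) ** 2)
        a_grid = np.linspace(300, 1100, 401)
        b_grid = np.linspace(2.0, 7.0, 401)
        preds = a_grid[:, None, None] * x[None, None, :] ** b_grid[None, :, None]
        ss = ((preds - y[None, None, :]) ** 2).sum(axis=-1)
        assert fit_ss <= ss.min() + 1e-6
        # and the grid-search minimiser agrees with the NLS parameters
        ia, ib = np.unravel_index(np.argmin(ss), ss.shape)
        assert p.a == pytest.approx(a_grid[ia], rel=0.02)
        assert p.b == pytest.approx(b_grid[ib], rel=0.02)

    def test_degenerate_input_flags_instead_of_raising(self):
        pairs = [(0.5, 100), (0.5, 120), (0.5, 140)]
        models = fit_candidates(pairs)
        assert all(not m.fit_ok for m in models)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_candidates([(0.5, 100), (0.6, 150)])


class TestSelectBest:
    def test_highest_r2_wins(self):
        power = CalibratedModel("power", 600.0, 4.0, r_squared=0.86)
        linear = CalibratedModel("linear", 500.0, 10.0, r_squared=0.60)
        assert select_best([linear, power]).form == "power"

    def test_single_model(self):
        m = CalibratedModel("linear", 1.0, 0.0, r_squared=0.5)
        assert select_best([m]) is m

    def test_tie_breaks_by_form_order(self):
        exp = CalibratedModel("exponential", 10.0, 2.0, r_squared=0.7)
        lin = CalibratedModel("linear", 1.0, 0.0, r_squared=0.7)
        assert select_best([exp, lin]).form == "linear"

    def test_all_failed_raises(self):
        bad = CalibratedModel("power", np.nan, np.nan, r_squared=-np.inf, fit_ok=False)
        with pytest.raises(ModelSelectionError):
            select_best([bad])


class TestValidate:
    def test_perfect_predictions(self):
        m = CalibratedModel("linear", 2.0, 0.0)
        rmse, rel = validate(m, [(1.0, 2.0), (2.0, 4.0)])
        assert rmse == 0.0 and rel == 0.0

    def test_hand_arithmetic(self):
        """obs (100, 200), est (110, 180): RMSE = sqrt(250) ≈ 15.811, rel = 10%."""
        m = CalibratedModel("linear", 1.0, 0.0)  # identity: est = x
        pairs = [(110.0, 100.0), (180.0, 200.0)]
        rmse, rel = validate(m, pairs)
        assert rmse == pytest.approx(np.sqrt((100 + 400) / 2))
        assert rmse == pytest.approx(15.8114, abs=1e-4)
        assert rel == pytest.approx(10.0)

    def test_zero_observation_excluded_from_relative_error(self, caplog):
        m = CalibratedModel("linear", 1.0, 0.0)
        rmse, rel = validate(m, [(5.0, 0.0), (100.0, 100.0)])
        assert rel == pytest.approx(0.0)
        assert rmse > 0


class TestPredictRaster:
    def _one_pixel(self, ndvi):
        grid = RasterGrid(1, 1, 0, 0, 250.0)
        return (Raster(grid, np.array([[ndvi]])), Raster.full(grid, 1.0))

    def test_published_model_at_ndvi_one(self):
        model = CalibratedModel("power", PUB_A, PUB_B)
        ndvi, mask = self._one_pixel(1.0)
        assert predict_raster(model, ndvi, mask).values[0, 0] == pytest.approx(PUB_A)

    def test_zero_ndvi_gives_zero(self):
        model = CalibratedModel("power", PUB_A, PUB_B)
        ndvi, mask = self._one_pixel(0.0)
        assert predict_raster(model, ndvi, mask).values[0, 0] == 0.0

    def test_ndvi_clipped_to_unit_interval(self):
        model = CalibratedModel("power", PUB_A, PUB_B)
        ndvi, mask = self._one_pixel(1.3)
        assert predict_raster(model, ndvi, mask).values[0, 0] == pytest.approx(PUB_A)

    def test_matches_scalar_loop_oracle_and_respects_mask(self, small_grid, rng):
        model = CalibratedModel("power", PUB_A, PUB_B)
        vals = rng.uniform(0, 1, small_grid.shape)
        vals[0, 1] = np.nan
        mask = rng.random(small_grid.shape) > 0.3
        out = predict_raster(model, Raster(small_grid, vals),
                             Raster.from_bool(small_grid, mask))
        for i in range(small_grid.nrows):
            for j in range(small_grid.ncols):
                if not mask[i, j] or np.isnan(vals[i, j]):
                    assert np.isnan(out.values[i, j])
                else:
                    assert out.values[i, j] == pytest.approx(PUB_A * vals[i, j] ** PUB_B)

    def test_monotone_in_ndvi_for_positive_exponent(self, rng):
        model = CalibratedModel("power", PUB_A, PUB_B)
        x = np.sort(rng.uniform(0, 1, 50))
        y = model.predict(x)
        assert np.all(np.diff(y) >= 0)

    def test_unfitted_model_raises(self):
        bad = CalibratedModel("power", np.nan, np.nan, fit_ok=False)
        ndvi, mask = self._one_pixel(0.5)
        with pytest.raises(RuntimeError):
            predict_raster(bad, ndvi, mask)


class TestRegionalSummary:
    def test_regional_scale_unit_arithmetic(self):
        """282.05 g·C/m² over 6.0e8 m² is ≈ 0.169 Tg·C."""
        n = 60  # 60×160 pixels of 250 m = 6.0e8 m²
        grid = RasterGrid(n, 160, 0, 0, 250.0)
        agb = Raster.full(grid, 282.05)
        mask = Raster.full(grid, 1.0)
        s = regional_summary(agb, mask)
        assert s.area_m2 == pytest.approx(6.0e8)
        assert s.total_TgC == pytest.approx(0.16923, abs=5e-5)

    def test_single_pixel_unit_conversion(self):
        grid = RasterGrid(1, 1, 0, 0, 250.0)
        s = regional_summary(Raster.full(grid, 1.0), Raster.full(grid, 1.0))
        assert s.area_m2 == 62500.0
        assert s.total_TgC == pytest.approx(6.25e-8)

    def test_matches_explicit_loop(self, small_grid, rng):
        vals = rng.uniform(50, 400, small_grid.shape)
        vals[1, 1] = np.nan
        mask = rng.random(small_grid.shape) > 0.4
        mask[1, 1] = True
        s = regional_summary(Raster(small_grid, vals), Raster.from_bool(small_grid, mask))
        total, count = 0.0, 0
        for i in range(small_grid.nrows):
            for j in range(small_grid.ncols):
                if mask[i, j] and not np.isnan(vals[i, j]):
                    total += vals[i, j]
                    count += 1
        assert s.mean_density == pytest.approx(total / count)
        assert s.area_m2 == mask.sum() * 250.0**2
        # scale consistency to machine precision
        assert s.total_TgC == s.mean_density * s.area_m2 * 1e-12

    def test_empty_mask_raises(self, small_grid):
        with pytest.raises(EmptyRegionError):
            regional_summary(Raster.full(small_grid, 1.0), Raster.full(small_grid, 0.0))


class TestSitesCsv:
    def test_roundtrip(self, tmp_path):
        sites = [SampleSite("P00", 100.0, 200.0, 2014, (80.0, 100.0, 120.0))]
        path = tmp_path / "sites.csv"
        write_sites_csv(sites, path)
        back = read_sites_csv(path)
        assert back[0].site_id == "P00"
        assert back[0].agb_density == pytest.approx(45.0)
        assert back[0].quadrat_biomass == (80.0, 100.0, 120.0)
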