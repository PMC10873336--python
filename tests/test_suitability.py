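"""Boolean suitability layers: thresholding, masking, combination."""

import numpy as np
import pytest

from plantwin import (
    LandClass,
    LandMask,
    Variable,
    combine_suitability,
    default_crop_parameters,
    static_environment_mask,
    threshold_suitability,
)
from plantwin.suitability import SuitabilityMap
from plantwin.windows import SeasonalGrid, make_window


@pytest.fixture
def window():
    return make_window(1, (2001, 2002))


def grid_of(geom, window, values, variable=Variable.RAINFALL, statistic="sum"):
    return SeasonalGrid(
        geometry=geom, window=window, variable=variable,
        statistic=statistic, values=np.asarray(values, dtype=float),
    )


class TestThreshold:
    @pytest.mark.parametrize(
        "value,lower,upper,expected",
        [
            (500.0, 300.0, 1600.0, 1.0),   # seasonal rainfall inside range
            (300.0, 300.0, 1600.0, 1.0),   # closed lower boundary
            (1600.0, 300.0, 1600.0, 1.0),  # closed upper boundary
            (299.999, 300.0, 1600.0, 0.0),
            (35.0, 17.0, 34.0, 0.0),       # seasonal mean temperature too hot
            (34.0, 17.0, 34.0, 1.0),
        ],
    )
    def test_closed_interval(self, geom4, window, value, lower, upper, expected):
        var = Variable.RAINFALL if upper > 100 else Variable.TEMPERATURE
        stat = "sum" if var is Variable.RAINFALL else "mean"
        grid = grid_of(geom4, window, np.full((4, 4), value), var, stat)
        smap = threshold_suitability(grid, lower, upper)
        np.testing.assert_array_equal(smap.values, expected)

    def test_nodata_propagates(self, geom4, window):
        values = np.full((4, 4), 500.0)
        values[2, 2] = np.nan
        smap = threshold_suitability(grid_of(geom4, window, values), 300, 1600)
        assert np.isnan(smap.values[2, 2])
        assert smap.values[0, 0] == 1.0

    def test_inverted_interval_rejected(self, geom4, window):
        with pytest.raises(ValueError, match="lower > upper"):
            threshold_suitability(grid_of(geom4, window, np.zeros((4, 4))), 10, 5)

    def test_widening_interval_is_monotone(self, geom4, window):
        rng = np.random.default_rng(1)
        grid = grid_of(geom4, window, rng.uniform(0, 2000, (4, 4)))
        narrow = threshold_suitability(grid, 400, 1200).values
        wide = threshold_suitability(grid, 300, 1600).values
        assert np.all(wide >= narrow)  # no 1 turns into 0


class TestStaticEnvironment:
    def test_all_criteria_pass(self, geom4):
        params = default_crop_parameters()
        env = {
            "slope": np.full((4, 4), 5.0),
            "elevation": np.full((4, 4), 900.0),
            "ph": np.full((4, 4), 6.8),
        }
        smap = static_environment_mask(env, params, geom4)
        np.testing.assert_array_equal(smap.values, 1.0)

    def test_steep_slope_fails(self, geom4):
        params = default_crop_parameters()
        smap = static_environment_mask({"slope": np.full((4, 4), 12.0)}, params, geom4)
        np.testing.assert_array_equal(smap.values, 0.0)

    def test_no_grids_is_identity(self, geom4):
        smap = static_environment_mask({}, default_crop_parameters(), geom4)
        np.testing.assert_array_equal(smap.values, 1.0)

    def test_criterion_without_parameter_is_error(self, geom4, tmp_path):
        from plantwin import load_crop_parameters

        f = tmp_path / "climate_only.yaml"
        f.write_text(
            "climate:\n  rain_season_mm: [300, 1600]\n  temp_c: [17, 34]\n  cycle_days: [90, 160]\n"
        )
        params = load_crop_parameters(f)
        with pytest.raises(ValueError, match="slope_max parameter unset"):
            static_environment_mask({"slope": np.zeros((4, 4))}, params, geom4)


class TestCombine:
    def make_layer(self, geom, window, value):
        return SuitabilityMap(geometry=geom, window=window,
                              values=np.full(geom.shape, value))

    def test_and_semantics(self, geom4, window, all_land):
        ones = self.make_layer(geom4, window, 1.0)
        zeros = self.make_layer(geom4, window, 0.0)
        assert combine_suitability([ones, ones], all_land).values[0, 0] == 1.0
        assert combine_suitability([ones, zeros], all_land).values[0, 0] == 0.0

    def test_water_cells_become_nodata_not_zero(self, geom4, window):
        classes = np.full(geom4.shape, int(LandClass.LAND))
        classes[1, 1] = int(LandClass.WATER)
        mask = LandMask(geometry=geom4, classes=classes)
        combined = combine_suitability([self.make_layer(geom4, window, 1.0)], mask)
        assert np.isnan(combined.values[1, 1])
        assert combined.values[0, 0] == 1.0

    def test_cropland_restriction_zeroes_plain_land(self, geom4, window):
        classes = np.full(geom4.shape, int(LandClass.LAND))
        classes[0, :] = int(LandClass.CROPLAND)
        mask = LandMask(geometry=geom4, classes=classes)
        combined = combine_suitability(
            [self.make_layer(geom4, window, 1.0)], mask, restrict_to_cropland=True
        )
        assert np.all(combined.values[0, :] == 1.0)
        assert np.all(combined.values[1:, :] == 0.0)

    def test_combining_with_all_ones_layer_is_idempotent(self, geom4, window, all_land):
        rng = np.random.default_rng(2)
        base = SuitabilityMap(
            geometry=geom4, window=window,
            values=(rng.uniform(size=geom4.shape) > 0.5).astype(float),
        )
        ones = self.make_layer(geom4, window, 1.0)
        combined = combine_suitability([base, ones], all_land)
        np.testing.assert_array_equal(combined.values, base.values)

    def test_empty_layer_list_rejected(self, all_land):
        with pytest.raises(ValueError, match="at least one"):
            combine_suitability([], all_land)


def test_pipeline_matches_per_cell_brute_force_oracle():
    """On a small grid the combined map must equal a literal per-cell loop
    re-deriving suitability from the raw monthly values."""
    from plantwin import (
        NoiseSpec,
        SyntheticSpec,
        aggregate_window,
        build_windows,
        generate_climate_fields,
        generate_landcover,
    )

    spec = SyntheticSpec(n_rows=12, n_cols=12, years=(2000, 2002),
                         noise_sd=NoiseSpec(), seed=21)
    rain, temp = generate_climate_fields(spec)
    mask = generate_landcover(spec)
    params = default_crop_parameters()
    for window in build_windows():
        rain_grid = aggregate_window(rain, window, "sum")
        temp_grid = aggregate_window(temp, window, "mean")
        combined = combine_suitability(
            [
                threshold_suitability(rain_grid, params.rain_season_min, params.rain_season_max),
                threshold_suitability(temp_grid, params.temp_min, params.temp_max),
            ],
            mask,
        )
        for i in range(12):
            for j in range(12):
                if mask.classes[i, j] == int(LandClass.WATER):
                    assert np.isnan(combined.values[i, j])
                    continue
                months = window.year_months()
                rsum = sum(rain.sel(y, m)[i, j] for y, m in months)
                tmean = sum(temp.sel(y, m)[i, j] for y, m in months) / len(months)
                expect = float(
                    params.rain_season_min <= rsum <= params.rain_season_max
                    and params.temp_min <= tmean <= params.temp_max
                )
                assert combined.values[i, j] == expect, (window.label, i, j)
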