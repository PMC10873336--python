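"""Area accounting, min-max normalization, and window ranking."""

import numpy as np
import pytest

from plantwin import (
    GridGeometry,
    LandClass,
    LandMask,
    cell_area_grid,
    minmax_normalize,
    rank_windows,
    suitable_percent,
)
from plantwin.ranking import EARTH_RADIUS_M, SeasonSummary
from plantwin.suitability import SuitabilityMap
from plantwin.windows import make_window


def square_geom(n, south, cell):
    return GridGeometry(
        n_rows=n, n_cols=n, lat_bounds=(south, south + n * cell),
        lon_bounds=(0.0, n * cell), cell_size=cell,
    )


class TestCellArea:
    def test_uniform_mode_constant(self, geom4):
        areas = cell_area_grid(geom4, "uniform", uniform_area_m2=1e6)
        np.testing.assert_array_equal(areas, 1e6)

    def test_cosine_ratio_between_equator_and_60_degrees(self):
        a_eq = cell_area_grid(square_geom(1, -0.5, 1.0), "cosine_lat")[0, 0]   # center 0 deg
        a_60 = cell_area_grid(square_geom(1, 59.5, 1.0), "cosine_lat")[0, 0]   # center 60 deg
        assert a_60 / a_eq == pytest.approx(0.5, rel=1e-12)

    def test_total_area_matches_analytic_band_formula(self):
        # oracle: area of a lat band over a lon span is R^2 * dlon * (sin(top)-sin(bottom))
        geom = square_geom(30, -15.0, 1.0)
        total = cell_area_grid(geom, "cosine_lat").sum()
        dlon = np.deg2rad(geom.n_cols * geom.cell_size)
        south, north = map(np.deg2rad, geom.lat_bounds)
        analytic = EARTH_RADIUS_M**2 * dlon * (np.sin(north) - np.sin(south))
        assert total == pytest.approx(analytic, rel=2e-4)


def boolean_map(geom, suitable_mask, window=None):
    values = suitable_mask.astype(float)
    return SuitabilityMap(geometry=geom, window=window, values=values)


class TestSuitablePercent:
    def test_quarter_suitable_uniform_grid(self):
        geom = square_geom(10, -5.0, 1.0)
        suitable = np.zeros((10, 10), dtype=bool)
        suitable.flat[:25] = True
        smap = boolean_map(geom, suitable, make_window(1, (2001, 2002)))
        s = suitable_percent(smap, cell_area_grid(geom, "uniform"), None)
        assert s.e == pytest.approx(25.0)
        assert s.b == 25
        assert s.e + s.nonsuitable_percent == pytest.approx(100.0)

    def test_no_suitable_cells(self, geom4):
        smap = boolean_map(geom4, np.zeros((4, 4), dtype=bool))
        s = suitable_percent(smap, cell_area_grid(geom4, "uniform"), None)
        assert s.e == 0.0 and s.nonsuitable_percent == 100.0

    def test_unequal_cell_areas_hand_arithmetic(self):
        # 4 land cells of areas (1,1,2,2)e6 m^2; the two 2e6 cells suitable
        geom = GridGeometry(n_rows=1, n_cols=4, lat_bounds=(0.0, 1.0),
                            lon_bounds=(0.0, 4.0), cell_size=1.0)
        areas = np.array([[1.0, 1.0, 2.0, 2.0]]) * 1e6
        smap = boolean_map(geom, np.array([[False, False, True, True]]))
        s = suitable_percent(smap, areas, None)
        assert s.e == pytest.approx(4.0 / 6.0 * 100.0)
        assert s.c == pytest.approx(4e6)

    def test_water_excluded_from_both_numerator_and_denominator(self, geom4):
        classes = np.full((4, 4), int(LandClass.LAND))
        classes[0, :] = int(LandClass.WATER)
        mask = LandMask(geometry=geom4, classes=classes)
        values = np.ones((4, 4))
        values[0, :] = np.nan  # water already NoData in the combined map
        smap = SuitabilityMap(geometry=geom4, window=None, values=values)
        s = suitable_percent(smap, cell_area_grid(geom4, "uniform"), mask)
        assert s.e == pytest.approx(100.0)  # all *land* suitable
        assert s.d == pytest.approx(12e6)

    def test_literal_formula_flag_reproduces_printed_form(self, geom4):
        smap = boolean_map(geom4, np.ones((4, 4), dtype=bool))
        areas = cell_area_grid(geom4, "uniform", uniform_area_m2=1e6)
        s = suitable_percent(smap, areas, None, formula="literal")
        # e = (a*b)/d * 1e6 with a=1e6, b=16, d=16e6
        assert s.e == pytest.approx((1e6 * 16) / 16e6 * 1e6)

    def test_zero_land_area_rejected(self, geom4):
        classes = np.full((4, 4), int(LandClass.WATER))
        mask = LandMask(geometry=geom4, classes=classes)
        values = np.full((4, 4), np.nan)
        smap = SuitabilityMap(geometry=geom4, window=None, values=values)
        with pytest.raises(ValueError, match="zero countable land"):
            suitable_percent(smap, cell_area_grid(geom4, "uniform"), mask)


class TestNormalizeAndRank:
    def test_endpoints_forced_to_unit_interval(self):
        np.testing.assert_allclose(minmax_normalize([0.05, 42.04]), [0.0, 1.0])
        np.testing.assert_allclose(minmax_normalize([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0])

    def test_affine_invariance(self):
        x = np.array([3.0, 7.5, 1.2, 9.9])
        np.testing.assert_allclose(minmax_normalize(x), minmax_normalize(4.0 * x - 17.0))

    def test_degenerate_input_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z = minmax_normalize([5.0, 5.0, 5.0])
        np.testing.assert_array_equal(z, 0.0)

    @staticmethod
    def summary(label, start_month, e):
        return SeasonSummary(
            window_label=label, start_month=start_month, a=1e6, b=0,
            c=e * 1e6, d=100e6, e=e, nonsuitable_percent=100.0 - e,
        )

    def test_rank_order_descending_e(self):
        table = rank_windows([
            self.summary("A", 1, 42.04),
            self.summary("B", 5, 0.05),
            self.summary("C", 9, 35.26),
        ])
        assert list(table["window"]) == ["A", "C", "B"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_tie_broken_by_earlier_start_month(self):
        with pytest.warns(UserWarning, match="degenerate"):  # equal e values
            table = rank_windows([
                self.summary("late", 6, 40.0),
                self.summary("early", 2, 40.0),
            ])
        assert list(table["window"]) == ["early", "late"]

    def test_rank_order_equals_descending_z_suitable(self):
        rng = np.random.default_rng(7)
        summaries = [self.summary(f"w{i}", i + 1, float(e))
                     for i, e in enumerate(rng.uniform(0, 50, 12))]
        table = rank_windows(summaries)
        assert list(table["z_suitable"]) == sorted(table["z_suitable"], reverse=True)
        assert table.iloc[0]["z_suitable"] == 1.0
        assert table.iloc[-1]["z_suitable"] == 0.0

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_windows([self.summary("X", 1, 10.0), self.summary("X", 2, 20.0)])


def test_monotone_consistency_superset_of_suitable_cells():
    """If window W's suitable set contains window V's, e(W) >= e(V)."""
    geom = square_geom(10, -5.0, 1.0)
    rng = np.random.default_rng(3)
    small = rng.uniform(size=(10, 10)) > 0.7
    big = small | (rng.uniform(size=(10, 10)) > 0.5)
    areas = cell_area_grid(geom, "cosine_lat")
    e_small = suitable_percent(boolean_map(geom, small), areas, None).e
    e_big = suitable_percent(boolean_map(geom, big), areas, None).e
    assert e_big >= e_small
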