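import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

import endolakes as el
from endolakes.accounting import (
    LABEL_CODES,
    UNLABELED,
    ClassedPolygon,
    PolygonSet,
    build_series,
    irrigated_area,
    max_ndvi_composite,
    population_series,
    rasterize,
    water_area,
)
from endolakes.core import QA_CLOUD, GridGeometry
from endolakes.endmembers import IndexGrid
from endolakes.unmix import FractionMap

from conftest import make_image


def fraction_map(water, geometry=None):
    """FractionMap with the given water-fraction grid (rest goes to upland)."""
    water = np.asarray(water, dtype=float)
    fractions = np.zeros(water.shape + (4,))
    fractions[..., 0] = water
    fractions[..., 2] = 1 - water
    return FractionMap(
        fractions=fractions,
        rmse=np.zeros(water.shape),
        valid=np.ones(water.shape, bool),
        names=el.ENDMEMBER_NAMES,
        geometry=geometry or GridGeometry(),
    )


class TestRasterize:
    def test_whole_grid_lake(self):
        polys = PolygonSet([ClassedPolygon(box(0, 0, 120, 120), "lake")])
        labels = rasterize(polys, GridGeometry(), (4, 4))
        assert (labels == LABEL_CODES["lake"]).all()

    def test_center_on_boundary_included(self):
        # pixel (0,0) center is (15,15); polygon edge passes through it
        polys = PolygonSet([ClassedPolygon(box(15, 15, 120, 120), "wetland")])
        labels = rasterize(polys, GridGeometry(), (2, 2))
        assert labels[0, 0] == LABEL_CODES["wetland"]

    def test_outside_unlabeled(self):
        polys = PolygonSet([ClassedPolygon(box(0, 0, 30, 30), "lake")])
        labels = rasterize(polys, GridGeometry(), (2, 2))
        assert labels[0, 0] == LABEL_CODES["lake"]
        assert labels[1, 1] == UNLABELED

    def test_excluded_wins_overlap(self):
        polys = PolygonSet(
            [
                ClassedPolygon(box(0, 0, 120, 120), "lake"),
                ClassedPolygon(box(0, 0, 60, 60), "excluded", subtype="reservoir"),
            ]
        )
        labels = rasterize(polys, GridGeometry(), (4, 4))
        assert labels[0, 0] == LABEL_CODES["excluded"]
        assert labels[3, 3] == LABEL_CODES["lake"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            ClassedPolygon(box(0, 0, 1, 1), "ocean")


class TestWaterArea:
    def test_two_by_two_worked_example(self):
        fm = fraction_map([[0.05, 0.20], [1.00, 0.00]])
        labels = np.full((2, 2), LABEL_CODES["lake"], dtype=np.int8)
        areas = water_area(fm, labels)
        assert areas["lake"] == pytest.approx(0.18)  # two pixels >= 0.10

    def test_all_zero_fractions(self):
        fm = fraction_map(np.zeros((3, 3)))
        labels = np.full((3, 3), LABEL_CODES["wetland"], dtype=np.int8)
        assert set(water_area(fm, labels).values()) == {0.0}

    def test_threshold_inclusive(self):
        fm = fraction_map([[0.10]])
        labels = np.full((1, 1), LABEL_CODES["lake"], dtype=np.int8)
        assert water_area(fm, labels)["lake"] == pytest.approx(0.09)

    def test_excluded_and_unlabeled_contribute_nothing(self):
        fm = fraction_map([[1.0, 1.0, 1.0]])
        labels = np.array(
            [[LABEL_CODES["excluded"], UNLABELED, LABEL_CODES["lake"]]], dtype=np.int8
        )
        assert water_area(fm, labels)["lake"] == pytest.approx(0.09)

    def test_invalid_pixels_not_counted(self):
        fm = fraction_map([[1.0, 1.0]])
        fm.valid[0, 0] = False
        labels = np.full((1, 2), LABEL_CODES["lake"], dtype=np.int8)
        assert water_area(fm, labels)["lake"] == pytest.approx(0.09)

    def test_misaligned_grids_error(self):
        fm = fraction_map(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="align"):
            water_area(fm, np.zeros((3, 3), dtype=np.int8))

    @given(t1=st.floats(0.01, 0.95), dt_=st.floats(0.01, 0.5))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, dt_):
        rng = np.random.default_rng(11)
        fm = fraction_map(rng.random((6, 6)))
        labels = np.full((6, 6), LABEL_CODES["lake"], dtype=np.int8)
        a1 = water_area(fm, labels, threshold=t1)["lake"]
        a2 = water_area(fm, labels, threshold=min(t1 + dt_, 1.0))["lake"]
        assert a2 <= a1

    def test_additive_over_partition(self):
        rng = np.random.default_rng(5)
        fm = fraction_map(rng.random((4, 4)))
        whole = PolygonSet([ClassedPolygon(box(0, 0, 120, 120), "lake")])
        left = PolygonSet([ClassedPolygon(box(0, 0, 60, 120), "lake")])
        right = PolygonSet([ClassedPolygon(box(60, 0, 120, 120), "lake")])
        g = GridGeometry()
        a_whole = water_area(fm, rasterize(whole, g, (4, 4)))["lake"]
        a_parts = (
            water_area(fm, rasterize(left, g, (4, 4)))["lake"]
            + water_area(fm, rasterize(right, g, (4, 4)))["lake"]
        )
        assert a_parts == pytest.approx(a_whole)


class TestMaxNdvi:
    def _img(self, nir, red, date, qa=None):
        shape = np.asarray(nir, dtype=float).shape
        return make_image(
            {"nir": np.asarray(nir, dtype=float), "red": np.asarray(red, dtype=float),
             "green": np.full(shape, 0.1)},
            qa=qa, date=date,
        )

    def test_single_image(self):
        img = self._img([[0.5]], [[0.1]], dt.date(2000, 6, 1))
        grid = max_ndvi_composite([img])
        assert grid.values[0, 0] == pytest.approx(2 / 3)

    def test_max_of_two(self):
        a = self._img([[0.3]], [[0.2]], dt.date(2000, 4, 1))  # ndvi 0.2
        b = self._img([[0.4]], [[0.1]], dt.date(2000, 8, 1))  # ndvi 0.6
        grid = max_ndvi_composite([a, b])
        assert grid.values[0, 0] == pytest.approx(0.6)

    def test_cloudy_high_value_skipped(self):
        qa = np.array([[QA_CLOUD]], dtype=np.uint8)
        high = self._img([[0.4]], [[0.1]], dt.date(2000, 8, 1), qa=qa)
        low = self._img([[0.3]], [[0.2]], dt.date(2000, 4, 1))
        grid = max_ndvi_composite([high, low])
        assert grid.values[0, 0] == pytest.approx(0.2)

    def test_window_filter(self):
        january = self._img([[0.9]], [[0.1]], dt.date(2000, 1, 15))
        with pytest.raises(ValueError, match="window"):
            max_ndvi_composite([january])

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            max_ndvi_composite([])


class TestIrrigatedArea:
    def test_strict_threshold_worked_example(self):
        vals = np.array([[0.39, 0.40, 0.41]])
        grid = IndexGrid(values=vals, kind="ndvi", valid=np.ones((1, 3), bool))
        labels = np.full((1, 3), LABEL_CODES["field"], dtype=np.int8)
        assert irrigated_area(grid, labels) == pytest.approx(0.09)  # only 0.41

    def test_no_field_pixels(self):
        vals = np.full((2, 2), 0.9)
        grid = IndexGrid(values=vals, kind="ndvi", valid=np.ones((2, 2), bool))
        labels = np.full((2, 2), LABEL_CODES["lake"], dtype=np.int8)
        assert irrigated_area(grid, labels) == 0.0

    def test_high_ndvi_outside_fields_excluded(self):
        vals = np.array([[0.9, 0.9]])
        grid = IndexGrid(values=vals, kind="ndvi", valid=np.ones((1, 2), bool))
        labels = np.array([[LABEL_CODES["field"], UNLABELED]], dtype=np.int8)
        assert irrigated_area(grid, labels) == pytest.approx(0.09)


class TestPopulationSeries:
    # exactly collinear at 2 persons/yr
    ANCHORS = {1975: 100.0, 1990: 130.0, 2000: 150.0, 2015: 180.0}

    def test_anchor_years_exact(self):
        df = population_series(self.ANCHORS, range(1975, 2019), 10.0)
        s = df.set_index("year")["population"]
        for year, value in self.ANCHORS.items():
            assert s[year] == pytest.approx(value, abs=1e-9)

    def test_collinear_anchors_linear(self):
        # natural cubic spline reproduces linear data exactly
        df = population_series(self.ANCHORS, [1995], 10.0)
        assert df["population"].iloc[0] == pytest.approx(140.0, abs=1e-6)

    def test_extrapolation_continues_terminal_cubic(self):
        df = population_series(self.ANCHORS, [2018], 10.0)
        assert df["population"].iloc[0] == pytest.approx(186.0, abs=1e-6)

    def test_density(self):
        df = population_series(self.ANCHORS, [1990], 50.0)
        assert df["density_km2"].iloc[0] == pytest.approx(130.0 / 50.0)

    def test_too_few_anchors(self):
        with pytest.raises(ValueError, match="4 anchors"):
            population_series({1975: 1.0, 1990: 2.0, 2000: 3.0}, [1980], 1.0)

    def test_nonpositive_area(self):
        with pytest.raises(ValueError, match="positive"):
            population_series(self.ANCHORS, [1980], 0.0)


class TestBuildSeries:
    def _population(self):
        return pd.DataFrame(
            {"year": [1984, 1985, 1986], "population": [10.0, 11.0, 12.0],
             "density_km2": [1.0, 1.1, 1.2]}
        )

    def test_missing_year_marked_not_dropped(self):
        water = {1984: dict(lake=1.0, wetland=0.5, peripheral_wetland=0.0),
                 1986: dict(lake=2.0, wetland=0.6, peripheral_wetland=0.0)}
        w, h = build_series("w1", "snowmelt", water, {1984: 3.0, 1986: 4.0},
                            self._population(), watershed_area_ha=100.0)
        assert sorted(w["year"].unique()) == [1984, 1985, 1986]
        gap = w.query("year == 1985")
        assert gap["area_ha"].isna().all()

    def test_irrigated_fraction_bounded(self):
        water = {1984: dict(lake=0.0, wetland=0.0, peripheral_wetland=0.0)}
        _, h = build_series("w1", "snowmelt", water, {1984: 30.0},
                            self._population(), watershed_area_ha=100.0)
        frac = h["irrigated_frac"].iloc[0]
        assert 0 <= frac <= 1 and frac == pytest.approx(0.3)

    def test_bad_region(self):
        with pytest.raises(ValueError, match="region"):
            build_series("w", "tropical", {}, {}, self._population(), 1.0)

    def test_full_pipeline_equals_truth(self, snowmelt_bundle):
        """Noiseless bundle: end-to-end areas equal truth exactly, all years."""
        water, human = el.run_bundle(snowmelt_bundle)
        truth = snowmelt_bundle.truth_areas.query("scene_available")
        merged = truth.merge(
            water, on=["watershed", "year", "class"], suffixes=("_truth", "_pipe")
        )
        assert len(merged) == len(truth)
        np.testing.assert_array_equal(
            merged["area_ha_truth"].to_numpy(), merged["area_ha_pipe"].to_numpy()
        )
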