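"""Spring climatology, climate envelope, range clipping and coverage."""

import numpy as np
import pandas as pd
import pytest

from gddphen import (
    ClimateEnvelope,
    Grid,
    GridGeoref,
    RangeMask,
    TemperatureStack,
    clip_range_to_envelope,
    envelope_from_points,
    load_range_geojson,
    percent_range_covered,
    rasterize_range,
    spring_climatology,
)
from gddphen.errors import (
    AlignmentError,
    DataCompletenessError,
    EmptyEnvelopeError,
    InputError,
)

GEO = GridGeoref(nrows=4, ncols=3, xllcorner=-90.0, yllcorner=38.0, cellsize=1.0)


def stack_with_monthly_means(year, means_by_month, georef=GEO, n_months=12):
    """Stack whose daily mean temperature is constant within each month."""
    from calendar import monthrange

    days = []
    for month in range(1, n_months + 1):
        ndays = monthrange(year, month)[1]
        days.extend([means_by_month.get(month, 15.0)] * ndays)
    tmean = np.array(days)[:, None, None] * np.ones(
        (1, georef.nrows, georef.ncols)
    )
    return TemperatureStack(georef=georef, year=year,
                            tmin=tmean - 5, tmax=tmean + 5)


class TestSpringClimatology:
    def test_mean_of_four_monthly_means(self):
        stack = stack_with_monthly_means(2015, {1: 2.0, 2: 4.0, 3: 6.0, 4: 8.0})
        spring = spring_climatology({2015: stack})
        assert np.allclose(spring.data, 5.0)

    def test_two_years_average(self):
        s1 = stack_with_monthly_means(2014, {1: 4.0, 2: 4.0, 3: 4.0, 4: 4.0})
        s2 = stack_with_monthly_means(2015, {1: 6.0, 2: 6.0, 3: 6.0, 4: 6.0})
        spring = spring_climatology({2014: s1, 2015: s2})
        assert np.allclose(spring.data, 5.0)

    def test_missing_month_is_completeness_error(self):
        short = stack_with_monthly_means(2015, {1: 2.0, 2: 4.0, 3: 6.0},
                                         n_months=3)  # no April
        with pytest.raises(DataCompletenessError):
            spring_climatology({2015: short})

    def test_missing_cell_propagates(self):
        stack = stack_with_monthly_means(2015, {1: 2.0, 2: 4.0, 3: 6.0, 4: 8.0})
        stack.tmin[:, 0, 0] = np.nan
        stack.tmax[:, 0, 0] = np.nan
        spring = spring_climatology({2015: stack})
        assert np.isnan(spring.data[0, 0])
        assert np.isfinite(spring.data[1:, :]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            spring_climatology({})


def grid_from(values):
    return Grid(georef=GEO, data=np.asarray(values, dtype=float))


def sites_at(latlons):
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(len(latlons))],
            "latitude": [ll[0] for ll in latlons],
            "longitude": [ll[1] for ll in latlons],
            "region": "",
        }
    )


class TestEnvelopeFromPoints:
    # grid rows: lat 41.5 (row 0), 40.5, 39.5, 38.5; cols: lon -89.5, -88.5, -87.5
    GRID = grid_from([[1.0, 2.0, 3.0],
                      [3.2, 5.5, 7.9],
                      [8.0, 9.0, 10.0],
                      [11.0, 12.0, 13.0]])

    def test_min_max_of_extracted_values(self):
        sites = sites_at([(40.5, -89.5), (40.5, -87.5), (40.5, -88.5)])
        env, rejects = envelope_from_points(self.GRID, sites)
        assert (env.t_min, env.t_max) == (3.2, 7.9)
        assert env.n_points == 3 and rejects == []

    def test_single_point_degenerate(self):
        env, _ = envelope_from_points(self.GRID, sites_at([(39.5, -88.5)]))
        assert env.t_min == env.t_max == 9.0

    def test_outside_grid_listed_not_fatal(self):
        sites = sites_at([(40.5, -88.5), (10.0, 0.0)])
        env, rejects = envelope_from_points(self.GRID, sites)
        assert rejects == ["s1"] and env.n_points == 1

    def test_all_rejected_is_error(self):
        grid = grid_from(np.full((4, 3), np.nan))
        with pytest.raises(EmptyEnvelopeError):
            envelope_from_points(grid, sites_at([(40.5, -88.5)]))

    def test_envelope_json_round_trip(self, tmp_path):
        env = ClimateEnvelope(t_min=3.2, t_max=7.9, n_points=3)
        env.save(tmp_path / "env.json")
        assert ClimateEnvelope.load(tmp_path / "env.json") == env


def full_mask(species="sp"):
    return RangeMask(georef=GEO, mask=np.ones((4, 3), bool), species=species)


class TestClipRangeToEnvelope:
    GRID = TestEnvelopeFromPoints.GRID

    def test_inclusive_interval(self):
        env = ClimateEnvelope(t_min=3.2, t_max=7.9, n_points=3)
        clipped = clip_range_to_envelope(full_mask(), self.GRID, env)
        # retained: 3.2, 5.5, 7.9 (row 1); 3.0 (row 0) is below t_min
        assert clipped.mask.sum() == 3
        assert clipped.mask[1].all()

    def test_envelope_spanning_all_values_is_identity(self):
        env = ClimateEnvelope(t_min=0.0, t_max=20.0, n_points=3)
        clipped = clip_range_to_envelope(full_mask(), self.GRID, env)
        assert np.array_equal(clipped.mask, full_mask().mask)

    def test_clip_is_idempotent(self):
        env = ClimateEnvelope(t_min=3.0, t_max=9.0, n_points=3)
        once = clip_range_to_envelope(full_mask(), self.GRID, env)
        twice = clip_range_to_envelope(once, self.GRID, env)
        assert np.array_equal(once.mask, twice.mask)

    def test_enlarging_envelope_never_shrinks_coverage(self):
        small = ClimateEnvelope(t_min=5.0, t_max=8.0, n_points=2)
        big = ClimateEnvelope(t_min=3.0, t_max=11.0, n_points=2)
        pct_small = percent_range_covered(
            clip_range_to_envelope(full_mask(), self.GRID, small), full_mask()
        )
        pct_big = percent_range_covered(
            clip_range_to_envelope(full_mask(), self.GRID, big), full_mask()
        )
        assert pct_big >= pct_small

    def test_calibration_cells_survive_clipping(self):
        sites = sites_at([(40.5, -89.5), (39.5, -87.5)])
        env, _ = envelope_from_points(self.GRID, sites)
        clipped = clip_range_to_envelope(full_mask(), self.GRID, env)
        for r in sites.itertuples():
            cell = GEO.cell_of(r.latitude, r.longitude)
            assert clipped.mask[cell]

    def test_misaligned_grids_rejected(self):
        other = GridGeoref(nrows=4, ncols=3, xllcorner=0.0, yllcorner=0.0,
                           cellsize=1.0)
        mask = RangeMask(georef=other, mask=np.ones((4, 3), bool))
        env = ClimateEnvelope(t_min=0, t_max=1, n_points=1)
        with pytest.raises(AlignmentError):
            clip_range_to_envelope(mask, self.GRID, env)


class TestPercentRangeCovered:
    def test_identity_is_100(self):
        assert percent_range_covered(full_mask(), full_mask()) == 100.0

    def test_half_of_equal_latitude_band_is_50(self):
        georef = GridGeoref(nrows=1, ncols=4, xllcorner=-90, yllcorner=40,
                            cellsize=1.0)
        full = RangeMask(georef=georef, mask=np.ones((1, 4), bool))
        half = RangeMask(georef=georef,
                         mask=np.array([[True, True, False, False]]))
        assert percent_range_covered(half, full) == pytest.approx(50.0)

    def test_matches_brute_force_cosine_weighting(self):
        rng = np.random.default_rng(3)
        full = RangeMask(georef=GEO, mask=np.ones((4, 3), bool))
        sub = RangeMask(georef=GEO, mask=rng.random((4, 3)) < 0.5)
        sub.mask &= full.mask
        w = np.cos(np.deg2rad(GEO.lat_centers))
        num = sum(w[r] for r in range(4) for c in range(3) if sub.mask[r, c])
        den = sum(w[r] for r in range(4) for c in range(3))
        expected = 100.0 * num / den
        assert percent_range_covered(sub, full) == pytest.approx(expected)

    def test_unweighted_mode_counts_cells(self):
        full = full_mask()
        sub = RangeMask(georef=GEO, mask=np.zeros((4, 3), bool))
        sub.mask[0, 0] = True
        assert percent_range_covered(sub, full, area_weighted=False) == \
            pytest.approx(100.0 / 12.0)

    def test_not_subset_rejected(self):
        sub = RangeMask(georef=GEO, mask=np.ones((4, 3), bool))
        full = RangeMask(georef=GEO, mask=np.zeros((4, 3), bool))
        full.mask[0, 0] = True
        with pytest.raises(InputError):
            percent_range_covered(sub, full)

    def test_empty_full_range_rejected(self):
        empty = RangeMask(georef=GEO, mask=np.zeros((4, 3), bool))
        with pytest.raises(InputError):
            percent_range_covered(empty, empty)


class TestLatitudinalGradient:
    def test_excluded_cells_form_extreme_latitude_bands(self):
        """With spring temperature monotone in latitude, the envelope keeps a
        contiguous latitudinal band and drops the extreme north and south."""
        georef = GridGeoref(nrows=20, ncols=5, xllcorner=-90, yllcorner=30,
                            cellsize=1.0)
        # warm south (high values at low row index? rows run N->S)
        temp = np.linspace(2.0, 16.0, 20)[:, None] * np.ones((1, 5))
        grid = Grid(georef=georef, data=temp)
        full = RangeMask(georef=georef, mask=np.ones((20, 5), bool))
        env = ClimateEnvelope(t_min=5.0, t_max=12.0, n_points=2)
        clipped = clip_range_to_envelope(full, grid, env)
        rows_kept = np.where(clipped.mask.any(axis=1))[0]
        # contiguous band
        assert np.array_equal(rows_kept,
                              np.arange(rows_kept.min(), rows_kept.max() + 1))
        # both extremes excluded
        assert not clipped.mask[0].any() and not clipped.mask[-1].any()
        # brute-force cell scan agrees exactly
        expected = (temp >= 5.0) & (temp <= 12.0)
        assert np.array_equal(clipped.mask, expected)


class TestRasterizeRange:
    def test_rectangle_center_membership(self):
        geojson = {
            "type": "Polygon",
            "coordinates": [[[-90, 38], [-88, 38], [-88, 40], [-90, 40],
                             [-90, 38]]],
        }
        geometry = load_range_geojson(geojson)
        mask = rasterize_range(geometry, GEO, species="sp")
        # cell centers inside lon [-90,-88] x lat [38,40]:
        # cols 0-1 (centers -89.5, -88.5), rows 2-3 (centers 39.5, 38.5)
        expected = np.zeros((4, 3), bool)
        expected[2:, :2] = True
        assert np.array_equal(mask.mask, expected)

    def test_feature_collection_union(self, tmp_path):
        import json

        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {},
                 "geometry": {"type": "Polygon",
                              "coordinates": [[[-90, 38], [-89, 38], [-89, 39],
                                               [-90, 39], [-90, 38]]]}},
                {"type": "Feature", "properties": {},
                 "geometry": {"type": "Polygon",
                              "coordinates": [[[-88, 41], [-87, 41], [-87, 42],
                                               [-88, 42], [-88, 41]]]}},
            ],
        }
        path = tmp_path / "range.geojson"
        path.write_text(json.dumps(fc))
        geometry = load_range_geojson(path)
        mask = rasterize_range(geometry, GEO)
        assert mask.mask[3, 0] and mask.mask[0, 2]
        assert mask.mask.sum() == 2
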