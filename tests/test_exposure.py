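"""Exposure operators against brute-force geometric and temporal oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

from uhimort import (
    ExposureSeries,
    PopulationGrid,
    RegionMask,
    RegularGrid,
    TemperatureField,
    daily_aggregate,
    daily_max_8h_running_mean,
    lag_mean,
    make_region_mask,
    population_weighted_series,
    regrid_conservative,
    uhii_stats,
)

import xarray as xr


def make_field(values, scenario="urban", start="2022-07-01"):
    values = np.asarray(values, dtype=float)
    nt, ny, nx = values.shape
    da = xr.DataArray(
        values, dims=("time", "y", "x"),
        coords={"time": pd.date_range(start, periods=nt, freq="h"),
                "y": 51.0 + 0.1 * np.arange(ny),
                "x": 0.1 * np.arange(nx)})
    return TemperatureField(da, scenario=scenario)


def hourly_series(vals, start="2022-07-01", **kw):
    idx = pd.date_range(start, periods=len(vals), freq="h")
    return ExposureSeries(pd.Series(np.asarray(vals, float), index=idx),
                          metric="hourly_mean", **kw)


def daily_series(vals, start="2022-07-01", metric="daily_mean"):
    idx = pd.date_range(start, periods=len(vals), freq="D")
    return ExposureSeries(pd.Series(np.asarray(vals, float), index=idx),
                          metric=metric)


class TestRegridConservative:
    def test_identity_regrid(self):
        grid = RegularGrid(np.arange(4.0), np.arange(3.0))
        pop = PopulationGrid(np.arange(12.0).reshape(3, 4), grid)
        out = regrid_conservative(pop, grid)
        np.testing.assert_allclose(out.counts, pop.counts, atol=1e-9)

    def test_polygon_split_in_half(self):
        target = RegularGrid(np.array([0.5, 1.5]), np.array([0.5]))
        src = [(box(0.0, 0.0, 2.0, 1.0), 1000.0)]
        out = regrid_conservative(src, target)
        np.testing.assert_allclose(out.counts, [[500.0, 500.0]], rtol=1e-12)

    def test_random_case_matches_geometric_oracle(self):
        rng = np.random.default_rng(3)
        src_grid = RegularGrid(np.linspace(0, 4, 5), np.linspace(0, 4, 5))
        counts = rng.uniform(0, 100, (5, 5))
        src = PopulationGrid(counts, src_grid)
        target = RegularGrid(np.linspace(0.3, 3.9, 3), np.linspace(0.1, 3.7, 3))
        out = regrid_conservative(src, target)
        # oracle: plain nested loop over all polygon pairs
        expected = np.zeros((3, 3))
        for iy in range(5):
            for ix in range(5):
                g = src_grid.cell_box(iy, ix)
                for jy in range(3):
                    for jx in range(3):
                        frac = g.intersection(target.cell_box(jy, jx)).area / g.area
                        expected[jy, jx] += counts[iy, ix] * frac
        np.testing.assert_allclose(out.counts, expected, rtol=1e-12)

    def test_total_conserved_when_target_covers_source(self):
        rng = np.random.default_rng(4)
        src_grid = RegularGrid(np.linspace(1, 3, 4), np.linspace(1, 3, 4))
        src = PopulationGrid(rng.uniform(0, 50, (4, 4)), src_grid)
        target = RegularGrid(np.linspace(0, 4, 9), np.linspace(0, 4, 9))
        out = regrid_conservative(src, target)
        assert out.total == pytest.approx(src.total, rel=1e-9)

    def test_disjoint_domains_error(self):
        src = [(box(100.0, 100.0, 101.0, 101.0), 10.0)]
        target = RegularGrid(np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValueError, match="overlap"):
            regrid_conservative(src, target)

    def test_invalid_geometry_named(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        target = RegularGrid(np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValueError, match="feature 0"):
            regrid_conservative([(bowtie, 10.0)], target)


class TestRegionMask:
    def test_covering_boundary_all_true(self):
        grid = RegularGrid(np.arange(4.0), np.arange(4.0))
        mask = make_region_mask(box(-1, -1, 4, 4), grid)
        assert mask.mask.all()

    def test_empty_intersection_error(self):
        grid = RegularGrid(np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError, match="boundary"):
            make_region_mask(box(10, 10, 11, 11), grid)

    def test_l_shape_matches_point_in_polygon(self):
        grid = RegularGrid(np.arange(4.0), np.arange(4.0))
        l_shape = Polygon([(-0.5, -0.5), (3.5, -0.5), (3.5, 1.5),
                           (1.5, 1.5), (1.5, 3.5), (-0.5, 3.5)])
        mask = make_region_mask(l_shape, grid)
        for iy in range(4):
            for ix in range(4):
                expected = Point(grid.x[ix], grid.y[iy]).within(l_shape)
                assert mask.mask[iy, ix] == expected


class TestPopulationWeighting:
    def test_uniform_population_is_unweighted_mean(self):
        rng = np.random.default_rng(0)
        field = make_field(rng.uniform(10, 30, (48, 3, 3)))
        pop = PopulationGrid(np.full((3, 3), 7.0), field.grid)
        mask = RegionMask(np.ones((3, 3), bool), field.grid)
        out = population_weighted_series(field, pop, mask)
        np.testing.assert_allclose(
            out.values.to_numpy(), field.values.mean(axis=(1, 2)), rtol=1e-12)

    def test_point_mass_selects_cell(self):
        rng = np.random.default_rng(1)
        field = make_field(rng.uniform(10, 30, (48, 3, 3)))
        counts = np.zeros((3, 3)); counts[1, 2] = 5.0
        pop = PopulationGrid(counts, field.grid)
        mask = RegionMask(np.ones((3, 3), bool), field.grid)
        out = population_weighted_series(field, pop, mask)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   field.values[:, 1, 2], rtol=1e-12)

    def test_matches_hand_computed_weighted_sum(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(10, 30, (24, 3, 3))
        w = rng.uniform(0, 10, (3, 3))
        field = make_field(vals)
        pop = PopulationGrid(w, field.grid)
        mask = RegionMask(np.ones((3, 3), bool), field.grid)
        out = population_weighted_series(field, pop, mask)
        expected = np.array([(vals[t] * w).sum() / w.sum() for t in range(24)])
        np.testing.assert_allclose(out.values.to_numpy(), expected, rtol=1e-12)

    def test_zero_masked_population_error(self):
        field = make_field(np.zeros((24, 3, 3)))
        counts = np.zeros((3, 3)); counts[0, 0] = 5.0
        pop = PopulationGrid(counts, field.grid)
        mask_arr = np.ones((3, 3), bool); mask_arr[0, 0] = False
        mask = RegionMask(mask_arr, field.grid)
        with pytest.raises(ValueError, match="population"):
            population_weighted_series(field, pop, mask)

    def test_permuting_storage_order_leaves_output_unchanged(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(10, 30, (24, 3, 3))
        w = rng.uniform(1, 10, (3, 3))
        field = make_field(vals)
        out1 = population_weighted_series(
            field, PopulationGrid(w, field.grid),
            RegionMask(np.ones((3, 3), bool), field.grid))
        # flip both axes: same cells, different storage order
        field2 = make_field(vals[:, ::-1, ::-1])
        out2 = population_weighted_series(
            field2, PopulationGrid(w[::-1, ::-1], field2.grid),
            RegionMask(np.ones((3, 3), bool), field2.grid))
        np.testing.assert_allclose(out1.values.to_numpy(),
                                   out2.values.to_numpy(), rtol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_weighted_mean_bounded_by_field_extremes(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-5, 40, (24, 3, 3))
        w = rng.uniform(0, 10, (3, 3))
        w.flat[rng.integers(0, 9)] += 1.0  # ensure nonzero total
        field = make_field(vals)
        out = population_weighted_series(
            field, PopulationGrid(w, field.grid),
            RegionMask(np.ones((3, 3), bool), field.grid))
        lo = vals.min(axis=(1, 2)) - 1e-9
        hi = vals.max(axis=(1, 2)) + 1e-9
        assert ((out.values.to_numpy() >= lo) & (out.values.to_numpy() <= hi)).all()


class TestDailyAggregate:
    def test_constant_series(self):
        out_mean = daily_aggregate(hourly_series([20.0] * 96), "mean")
        out_max = daily_aggregate(hourly_series([20.0] * 96), "max")
        assert (out_mean.values == 20.0).all()
        assert (out_max.values == 20.0).all()
        assert len(out_mean) == 4

    def test_one_day_arithmetic(self):
        out = daily_aggregate(hourly_series(np.arange(1, 25)), "mean")
        assert out.values.iloc[0] == pytest.approx(12.5)
        out = daily_aggregate(hourly_series(np.arange(1, 25)), "max")
        assert out.values.iloc[0] == 24

    def test_matches_per_day_recomputation(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(5, 35, 240)
        s = hourly_series(vals)
        out = daily_aggregate(s, "mean")
        for d in range(10):
            assert out.values.iloc[d] == pytest.approx(
                vals[d * 24:(d + 1) * 24].mean(), rel=1e-12)

    def test_incomplete_day_dropped(self):
        s = hourly_series(np.arange(48.0))
        sparse = ExposureSeries(s.values.drop(s.values.index[:10]),
                                metric="hourly_mean")
        out = daily_aggregate(sparse, "mean")
        assert len(out) == 1  # first day has 14 < 18 hours

    def test_empty_error(self):
        empty = ExposureSeries(pd.Series([], dtype=float,
                                         index=pd.DatetimeIndex([])),
                               metric="hourly_mean")
        with pytest.raises(ValueError):
            daily_aggregate(empty, "mean")


class TestLagMean:
    def test_constant_series_drops_two_days(self):
        out = lag_mean(daily_series([21.0] * 10))
        assert len(out) == 8
        assert (out.values == 21.0).all()

    def test_three_day_arithmetic(self):
        out = lag_mean(daily_series([20.0, 22.0, 24.0]))
        assert len(out) == 1
        assert out.values.iloc[0] == pytest.approx(22.0)

    def test_matches_rolling_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(10, 30, 30)
        out = lag_mean(daily_series(vals))
        for i in range(2, 30):
            assert out.values.iloc[i - 2] == pytest.approx(
                vals[i - 2:i + 1].mean(), rel=1e-12)

    def test_linear_series_shifted_by_one_slope(self):
        # lag mean of a+b*d is a+b*(d-1): exactly one day's slope behind
        b = 0.7
        vals = 15.0 + b * np.arange(12)
        out = lag_mean(daily_series(vals))
        np.testing.assert_allclose(out.values.to_numpy(),
                                   vals[2:] - b, rtol=1e-12)

    def test_short_series_error(self):
        with pytest.raises(ValueError, match="3 days"):
            lag_mean(daily_series([20.0, 21.0]))

    def test_gap_error(self):
        s = daily_series([20.0] * 6)
        gappy = ExposureSeries(s.values.drop(s.values.index[3]),
                               metric="daily_mean")
        with pytest.raises(ValueError, match="gap"):
            lag_mean(gappy)


class TestDailyMax8hMean:
    def test_constant_concentration(self):
        out = daily_max_8h_running_mean(hourly_series([50.0] * 96).values)
        assert (out.values == 50.0).all()

    def test_single_spike_middle_day(self):
        vals = np.zeros(72)
        vals[36] = 80.0  # mid second day
        out = daily_max_8h_running_mean(hourly_series(vals).values)
        assert out.values.iloc[1] == pytest.approx(10.0)

    def test_matches_exhaustive_window_enumeration(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 100, 120)
        s = hourly_series(vals).values
        out = daily_max_8h_running_mean(s)
        # oracle: enumerate all 8-h windows ending in each day
        for d in range(5):
            best = -np.inf
            for end in range(d * 24, (d + 1) * 24):
                lo = max(0, end - 7)
                window = vals[lo:end + 1]
                if len(window) >= 6:
                    best = max(best, window.mean())
            if np.isfinite(best):
                assert out.values.iloc[d] == pytest.approx(best, rel=1e-12)

    def test_at_least_daily_mean(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 60, 96)
        s = hourly_series(vals).values
        out = daily_max_8h_running_mean(s)
        daily_mean = s.groupby(s.index.normalize()).mean()
        assert (out.values >= daily_mean.reindex(out.values.index) - 1e-9).all()

    def test_negative_concentration_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            daily_max_8h_running_mean(hourly_series([-1.0] * 48).values)


class TestUhiiStats:
    def test_identical_scenarios_zero(self):
        s = hourly_series([20.0] * 48, scenario="urban")
        t = hourly_series([20.0] * 48, scenario="non-urban")
        out = uhii_stats(s, t)
        assert out.minimum == out.mean == out.maximum == 0.0

    def test_constant_offset(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(10, 30, 48)
        u = hourly_series(base + 2.0, scenario="urban")
        n = hourly_series(base, scenario="non-urban")
        out = uhii_stats(u, n)
        assert out.minimum == pytest.approx(2.0)
        assert out.maximum == pytest.approx(2.0)

    def test_synthetic_summary_matches_raw_arrays(self, bundle, results):
        d = (results.exposures["urban"]["hourly"].values
             - results.exposures["non-urban"]["hourly"].values).to_numpy()
        assert results.uhii.minimum == pytest.approx(d.min())
        assert results.uhii.mean == pytest.approx(d.mean())
        assert results.uhii.maximum == pytest.approx(d.max())
        # maps: brute recomputation of the day/night mean difference
        inp = bundle.inputs
        diff = inp.urban.values - inp.non_urban.values
        hours = inp.urban.times.hour.to_numpy()
        day = (hours >= 8) & (hours < 20)
        np.testing.assert_allclose(results.uhii.map_day.values,
                                   diff[day].mean(axis=0), rtol=1e-10)
        np.testing.assert_allclose(results.uhii.map_night.values,
                                   diff[~day].mean(axis=0), rtol=1e-10)

    def test_misaligned_error(self):
        u = hourly_series([20.0] * 48, scenario="urban")
        n = hourly_series([20.0] * 48, start="2022-07-02",
                          scenario="non-urban")
        with pytest.raises(ValueError, match="misaligned"):
            uhii_stats(u, n)


def test_weighting_and_daily_mean_commute(bundle):
    """Population-weight then daily-mean equals daily-mean then weight."""
    inp = bundle.inputs
    from uhimort import make_region_mask
    mask = make_region_mask(inp.boundary, inp.urban.grid)
    hourly = population_weighted_series(inp.urban, inp.population, mask)
    a = daily_aggregate(hourly, "mean").values
    # other order: per-cell daily means, then population weighting
    w = inp.population.counts[mask.mask]
    cells = inp.urban.values[:, mask.mask]
    per_cell_daily = pd.DataFrame(cells, index=inp.urban.times) \
        .groupby(lambda t: t.normalize()).mean()
    b = (per_cell_daily @ w) / w.sum()
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)
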