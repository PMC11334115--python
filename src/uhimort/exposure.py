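"""Exposure construction: from gridded scenario fields to regional series.

This module turns hourly gridded temperature for each scenario into the
regional population-weighted exposure series that the exposure-response
functions consume:

* conservative area-weighted regridding of population counts onto the
  model grid (counts are extensive: each source count is split across
  target cells in proportion to geometric overlap, preserving totals);
* a binary region mask from a boundary polygon (a cell is included iff
  its centre lies inside the polygon);
* population-weighted spatial averaging restricted to the mask;
* temporal operators: daily mean/max aggregation with a completeness
  rule, the 0-2 day lag mean driving the heat exposure-response, and the
  daily maximum 8-hour running mean used for pollutant exposure;
* urban-heat-island-intensity summaries (hourly population-weighted
  urban minus non-urban difference, plus per-cell day/night mean maps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import xarray as xr
import shapely
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

from .grids import (
    ExposureSeries,
    PopulationGrid,
    RegionMask,
    RegularGrid,
    TemperatureField,
)

logger = logging.getLogger(__name__)

# Day/night split used for the intensity maps: day is 08:00-20:00 local,
# night the complementary hours, matching the convention of the study design.
DAY_HOURS = (8, 20)

#: Minimum fraction of hours required for a daily aggregate.
DAILY_COMPLETENESS = 0.75
#: An 8-hour running-mean window is valid with at least 6 of 8 hours.
WINDOW_MIN_HOURS = 6
#: A day needs at least this many valid 8-hour windows.
DAY_MIN_WINDOWS = 18


def regrid_conservative(
    source: Union[PopulationGrid, Sequence[tuple[BaseGeometry, float]]],
    target: RegularGrid,
) -> PopulationGrid:
    """Transfer population counts onto ``target`` by conservative area weighting.

    ``source`` is either a :class:`PopulationGrid` (its cells become source
    polygons) or a sequence of ``(geometry, count)`` pairs, e.g. census
    output areas.  Each source count is split across target cells in
    proportion to the overlap area, so the total over cells that intersect
    the target domain is conserved.

    Raises ``ValueError`` if a source geometry is invalid (naming the
    offending feature) or if no source overlaps the target domain.
    """
    if isinstance(source, PopulationGrid):
        pairs = [
            (source.grid.cell_box(iy, ix), source.counts[iy, ix])
            for iy in range(source.grid.shape[0])
            for ix in range(source.grid.shape[1])
        ]
    else:
        pairs = list(source)

    ny, nx = target.shape
    boxes = [target.cell_box(iy, ix) for iy in range(ny) for ix in range(nx)]
    tree = STRtree(boxes)
    out = np.zeros(ny * nx)
    any_overlap = False
    for i, (geom, count) in enumerate(pairs):
        if geom is None or geom.is_empty:
            continue
        if not geom.is_valid:
            raise ValueError(f"invalid source geometry at feature {i}")
        area = geom.area
        if area == 0 or count == 0:
            continue
        for j in tree.query(geom, predicate="intersects"):
            frac = geom.intersection(boxes[j]).area / area
            if frac > 0:
                out[j] += count * frac
                any_overlap = True
    if not any_overlap:
        raise ValueError("source population does not overlap the target grid")
    return PopulationGrid(out.reshape(ny, nx), target)


def make_region_mask(boundary: BaseGeometry, grid: RegularGrid) -> RegionMask:
    """Mask of cells whose centre lies inside ``boundary``."""
    if not boundary.is_valid:
        raise ValueError("boundary polygon is invalid")
    lon, lat = grid.cell_centres()
    inside = shapely.contains_xy(boundary, lon.ravel(), lat.ravel())
    inside = inside.reshape(grid.shape)
    if not inside.any():
        raise ValueError("boundary does not contain any grid cell centre")
    return RegionMask(inside, grid)


def population_weighted_series(
    field: TemperatureField,
    pop: PopulationGrid,
    mask: RegionMask,
) -> ExposureSeries:
    """Hourly regional mean of ``field`` weighted by masked population.

    value(t) = sum_i w_i T_i(t) / sum_i w_i over cells i in the mask.
    """
    if not (field.grid.same_as(pop.grid) and field.grid.same_as(mask.grid)):
        raise ValueError("field, population and mask must share a grid")
    w = pop.counts[mask.mask]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("masked population is zero; weighted mean undefined")
    arr = field.values[:, mask.mask]  # (time, n_masked)
    vals = arr @ (w / wsum)
    series = pd.Series(vals, index=field.times)
    return ExposureSeries(series, metric="hourly_mean", units="degC",
                          scenario=field.scenario)


def daily_aggregate(hourly: ExposureSeries, stat: str = "mean") -> ExposureSeries:
    """Collapse an hourly series to one value per calendar day.

    A day is kept only if at least 75% of its hours are present; incomplete
    days are dropped and logged.  ``stat`` is ``"mean"`` or ``"max"``.
    """
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    if len(hourly.values) == 0:
        raise ValueError("empty hourly series")
    s = hourly.values.dropna()
    by_day = s.groupby(s.index.normalize())
    counts = by_day.count()
    agg = by_day.mean() if stat == "mean" else by_day.max()
    need = int(np.ceil(24 * DAILY_COMPLETENESS))
    keep = counts >= need
    for day in counts.index[~keep]:
        logger.info("dropping day %s: only %d hours present", day.date(),
                    counts[day])
    agg = agg[keep]
    if agg.empty:
        raise ValueError("no day satisfies the completeness rule")
    metric = "daily_mean" if stat == "mean" else "daily_max"
    return ExposureSeries(agg, metric=metric, units=hourly.units,
                          scenario=hourly.scenario)


def lag_mean(daily: ExposureSeries, lags: Iterable[int] = (0, 1, 2)) -> ExposureSeries:
    """0-2 day lag mean: mean of today's and the two previous days' values.

    The first two days of the record carry incomplete lag windows and are
    excluded; no partial-window fallback is applied.  Requires a gap-free
    daily series of at least three days.
    """
    if sorted(lags) != [0, 1, 2]:
        raise ValueError("only the 0-2 day lag window is supported")
    if not daily.is_daily:
        raise ValueError("lag_mean expects a daily series")
    s = daily.values
    if len(s) < 3:
        raise ValueError("lag mean needs at least 3 days")
    gaps = pd.date_range(s.index[0], s.index[-1], freq="D").difference(s.index)
    if len(gaps):
        raise ValueError(f"daily series has gaps ({gaps[0].date()} missing)")
    out = s.rolling(window=3).mean().dropna()
    return ExposureSeries(out, metric="lag012_mean", units=daily.units,
                          scenario=daily.scenario)


def daily_max_8h_running_mean(hourly: Union[ExposureSeries, pd.Series]) -> ExposureSeries:
    """Daily maximum 8-hour running mean of an hourly concentration series.

    Each 8-hour window is labelled by its ending hour and attributed to the
    day containing that ending hour; a window is valid with at least 6 of
    its 8 hours present, and a day is reported only if it has at least 18
    valid windows (otherwise it is dropped and logged).
    """
    if isinstance(hourly, ExposureSeries):
        s = hourly.values
        units = hourly.units
    else:
        s = hourly
        units = "ugm3"
    if len(s) == 0:
        raise ValueError("empty concentration series")
    if (s.dropna() < 0).any():
        raise ValueError("concentrations must be non-negative")
    # reindex to a full hourly axis so missing hours count against windows
    full = pd.date_range(s.index[0], s.index[-1], freq="h")
    s = s.reindex(full)
    roll = s.rolling(window=8, min_periods=WINDOW_MIN_HOURS).mean()
    day = roll.index.normalize()
    valid = roll.notna()
    out = {}
    for d, grp in roll.groupby(day):
        nvalid = int(valid.loc[grp.index].sum())
        if nvalid >= DAY_MIN_WINDOWS:
            out[d] = grp.max()
        else:
            logger.info("dropping day %s: only %d valid 8-h windows",
                        d.date(), nvalid)
    if not out:
        raise ValueError("no day has enough valid 8-hour windows")
    res = pd.Series(out).sort_index()
    return ExposureSeries(res, metric="daily_max_8h_mean", units=units)


@dataclass
class UhiiSummary:
    """Urban-heat-island-intensity summary.

    ``minimum``/``mean``/``maximum`` describe the hourly population-weighted
    urban minus non-urban temperature difference; the map attributes are
    per-cell mean differences over all hours, daytime hours (08-20) and
    nighttime hours (20-08).
    """

    minimum: float
    mean: float
    maximum: float
    map_all: Optional[xr.DataArray] = None
    map_day: Optional[xr.DataArray] = None
    map_night: Optional[xr.DataArray] = None

    def as_dict(self) -> dict:
        return {"uhii_min": self.minimum, "uhii_mean": self.mean,
                "uhii_max": self.maximum}


def uhii_stats(
    urban: ExposureSeries,
    non_urban: ExposureSeries,
    urban_field: Optional[TemperatureField] = None,
    non_urban_field: Optional[TemperatureField] = None,
) -> UhiiSummary:
    """Summarise the urban minus non-urban difference.

    The scalar statistics come from the hourly population-weighted series;
    if the gridded fields are supplied the per-cell mean-difference maps
    (all hours / day / night) are attached too.
    """
    if not urban.values.index.equals(non_urban.values.index):
        raise ValueError("urban and non-urban series are misaligned")
    diff = urban.values - non_urban.values
    maps = {}
    if urban_field is not None and non_urban_field is not None:
        if not urban_field.grid.same_as(non_urban_field.grid):
            raise ValueError("scenario fields are on different grids")
        if not urban_field.times.equals(non_urban_field.times):
            raise ValueError("scenario fields are misaligned in time")
        d = urban_field.data - non_urban_field.data
        hours = urban_field.times.hour
        is_day = (hours >= DAY_HOURS[0]) & (hours < DAY_HOURS[1])
        maps["map_all"] = d.mean("time")
        maps["map_day"] = d.isel(time=np.where(is_day)[0]).mean("time")
        maps["map_night"] = d.isel(time=np.where(~is_day)[0]).mean("time")
    return UhiiSummary(
        minimum=float(diff.min()),
        mean=float(diff.mean()),
        maximum=float(diff.max()),
        **maps,
    )
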