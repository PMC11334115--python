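"""Readers and writers for the on-disk interchange formats.

Gridded temperature travels as CF-style NetCDF (dims ``time, y, x``,
variable ``tas`` stored in kelvin with a ``units`` attribute; ingestion
accepts kelvin or Celsius and normalises to Celsius).  Mortality,
pollutant and station series are plain CSV; the region boundary is
GeoJSON.  All readers fail loudly on malformed input rather than
repairing it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grids import PopulationGrid, RegularGrid, TemperatureField
from .hia import MortalitySeries
from .validation import StationRecord

KELVIN_OFFSET = 273.15
_CELSIUS_UNITS = {"degC", "deg_C", "C", "celsius", "degree_Celsius", "°C"}
_KELVIN_UNITS = {"K", "kelvin", "Kelvin"}

PathLike = Union[str, Path]


# -- gridded temperature -----------------------------------------------------

def write_gridded(field: TemperatureField, path: PathLike) -> None:
    """Write a temperature field as CF NetCDF (kelvin)."""
    da = field.data + KELVIN_OFFSET
    da = da.assign_attrs(units="K", standard_name="air_temperature")
    ds = xr.Dataset({"tas": da}, attrs={"scenario": field.scenario})
    ds.to_netcdf(path, engine="scipy")


def read_gridded(path: PathLike, scenario: str | None = None) -> TemperatureField:
    """Read and validate a gridded temperature file, normalised to degC.

    Fails with a specific message on a missing units attribute, NaN
    blocks, or a non-monotone / non-hourly time axis.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    if "tas" in ds:
        da = ds["tas"]
    else:
        names = [v for v in ds.data_vars if set(ds[v].dims) >= {"time", "y", "x"}]
        if not names:
            raise ValueError(f"{path}: no (time, y, x) temperature variable")
        da = ds[names[0]]
    units = da.attrs.get("units")
    if units is None:
        raise ValueError(f"{path}: temperature variable has no units attribute")
    if units in _KELVIN_UNITS:
        da = da - KELVIN_OFFSET
    elif units not in _CELSIUS_UNITS:
        raise ValueError(f"{path}: unrecognised temperature units {units!r}")
    if bool(np.isnan(da.values).any()):
        raise ValueError(f"{path}: temperature field contains NaN")
    scen = scenario or ds.attrs.get("scenario")
    if scen is None:
        raise ValueError(f"{path}: scenario neither in file nor given")
    da = da.transpose("time", "y", "x")
    da.attrs.pop("units", None)
    try:
        return TemperatureField(da, scenario=scen)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# -- population --------------------------------------------------------------

def write_population(pop: PopulationGrid, path: PathLike) -> None:
    da = xr.DataArray(pop.counts, coords={"y": pop.grid.y, "x": pop.grid.x},
                      dims=("y", "x"), name="population",
                      attrs={"units": "1", "long_name": "resident count"})
    xr.Dataset({"population": da}).to_netcdf(path, engine="scipy")


def read_population(path: PathLike) -> PopulationGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    if "population" not in ds:
        raise ValueError(f"{path}: no 'population' variable")
    da = ds["population"]
    grid = RegularGrid(da["x"].values, da["y"].values)
    return PopulationGrid(da.values, grid)


# -- boundary ----------------------------------------------------------------

def write_boundary(boundary: BaseGeometry, path: PathLike) -> None:
    gj = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": {"name": "region"},
                        "geometry": mapping(boundary)}]}
    Path(path).write_text(json.dumps(gj))


def read_boundary(path: PathLike) -> BaseGeometry:
    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        feats = gj.get("features", [])
        if not feats:
            raise ValueError(f"{path}: empty FeatureCollection")
        geom = shape(feats[0]["geometry"])
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if not geom.is_valid:
        raise ValueError(f"{path}: invalid boundary geometry")
    return geom


# -- mortality ---------------------------------------------------------------

def write_mortality(mortality: MortalitySeries, path: PathLike) -> None:
    long = (mortality.deaths.rename_axis("date")
            .reset_index()
            .melt(id_vars="date", var_name="age_group", value_name="deaths")
            .sort_values(["date", "age_group"], kind="stable"))
    long["date"] = long["date"].dt.strftime("%Y-%m-%d")
    long.to_csv(path, index=False)


def read_mortality(path: PathLike) -> MortalitySeries:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "age_group", "deaths"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: mortality CSV needs columns {sorted(required)}")
    df = df[df["age_group"] != "all"]
    wide = df.pivot(index="date", columns="age_group", values="deaths")
    wide.columns.name = None
    return MortalitySeries(wide)


# -- pollutants --------------------------------------------------------------

def write_pollution(conc: pd.DataFrame, path: PathLike) -> None:
    long = (conc.rename_axis("timestamp").reset_index()
            .melt(id_vars="timestamp", var_name="pollutant",
                  value_name="concentration_ugm3")
            .sort_values(["timestamp", "pollutant"], kind="stable"))
    long["timestamp"] = long["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    long.to_csv(path, index=False)


def read_pollution(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "pollutant", "concentration_ugm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pollutant CSV needs columns {sorted(required)}")
    wide = df.pivot(index="timestamp", columns="pollutant",
                    values="concentration_ugm3")
    wide.columns.name = None
    return wide


# -- stations ----------------------------------------------------------------

def write_stations(stations: Sequence[StationRecord], path: PathLike) -> None:
    frames = []
    for st in stations:
        frames.append(pd.DataFrame({
            "station_id": st.station_id, "network": st.network,
            "lat": st.lat, "lon": st.lon,
            "timestamp": st.series.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature_C": st.series.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stations(path: PathLike) -> list[StationRecord]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"station_id", "network", "lat", "lon", "timestamp",
                "temperature_C"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: station CSV needs columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        series = pd.Series(grp["temperature_C"].to_numpy(),
                           index=pd.DatetimeIndex(grp["timestamp"]))
        out.append(StationRecord(
            station_id=str(sid), lat=float(grp["lat"].iloc[0]),
            lon=float(grp["lon"].iloc[0]),
            network=str(grp["network"].iloc[0]), series=series.sort_index()))
    return out
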