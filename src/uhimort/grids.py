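"""Containers for gridded fields, population grids, masks and exposure series.

The analysis operates on a single regular latitude/longitude grid: hourly
2-m air temperature fields for two scenarios (urban and counterfactual
non-urban), a population-count grid on the same cells, and a boolean region
mask derived from a boundary polygon.  Time series extracted from these
grids are carried as :class:`ExposureSeries`, which records which exposure
metric the values represent (hourly mean, daily mean, 0-2 day lag mean,
daily maximum 8-hour running mean, or daily maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box

EXPOSURE_METRICS = (
    "hourly_mean",
    "daily_mean",
    "lag012_mean",
    "daily_max_8h_mean",
    "daily_max",
)

SCENARIOS = ("urban", "non-urban")


@dataclass(frozen=True)
class RegularGrid:
    """Cell-centre coordinates of a regular rectangular grid.

    ``x`` are longitudes and ``y`` latitudes of cell centres, both strictly
    increasing with uniform spacing.  Cell polygons are axis-aligned boxes
    of size (dx, dy) centred on the coordinates.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.size == 0 or y.size == 0:
            raise ValueError("degenerate grid: empty coordinate axis")
        for name, c in (("x", x), ("y", y)):
            if c.size > 1:
                d = np.diff(c)
                if np.any(d <= 0):
                    raise ValueError(f"grid axis {name} must be strictly increasing")
                if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
                    raise ValueError(f"grid axis {name} is not regular")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 1.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 1.0

    def cell_box(self, iy: int, ix: int):
        """Shapely polygon of the cell at row ``iy``, column ``ix``."""
        hx, hy = self.dx / 2.0, self.dy / 2.0
        cx, cy = self.x[ix], self.y[iy]
        return box(cx - hx, cy - hy, cx + hx, cy + hy)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (lon, lat) of all cell centres, shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    def same_as(self, other: "RegularGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
        )


def _check_hourly_time(times: pd.DatetimeIndex) -> None:
    if len(times) < 2:
        raise ValueError("field needs at least two timestamps")
    deltas = np.diff(times.values)
    if np.any(deltas.astype("timedelta64[s]").astype(int) <= 0):
        raise ValueError("time axis must be strictly increasing")
    if len(set(deltas)) != 1 or deltas[0] != np.timedelta64(1, "h"):
        raise ValueError("time axis must be hourly and equally spaced")


@dataclass
class TemperatureField:
    """Hourly 2-m air temperature on a regular grid for one scenario.

    ``data`` holds temperature in degrees Celsius with dims (time, y, x);
    the time axis is hourly, strictly increasing and gap-free, and the
    field contains no NaN.
    """

    data: xr.DataArray
    scenario: str

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("time", "y", "x"):
            raise ValueError("field dims must be (time, y, x)")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        _check_hourly_time(self.times)
        if bool(np.isnan(self.data.values).any()):
            raise ValueError("temperature field contains NaN")
        self.grid  # validates coordinate regularity

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def grid(self) -> RegularGrid:
        return RegularGrid(self.data["x"].values, self.data["y"].values)

    @property
    def values(self) -> np.ndarray:
        return self.data.values


@dataclass
class PopulationGrid:
    """Resident counts per grid cell (extensive quantity, persons)."""

    counts: np.ndarray
    grid: RegularGrid

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.grid.shape:
            raise ValueError("population counts do not match grid shape")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class RegionMask:
    """Boolean cell-inclusion mask derived from a boundary polygon."""

    mask: np.ndarray
    grid: RegularGrid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask does not match grid shape")
        if not self.mask.any():
            raise ValueError("region mask selects no cells")


@dataclass
class ExposureSeries:
    """A regional exposure time series with its metric label.

    ``values`` is a pandas Series with a DatetimeIndex -- hourly for the
    ``hourly_mean`` metric, one entry per calendar day otherwise.  ``units``
    is ``degC`` for temperature metrics and ``ugm3`` for concentrations.
    """

    values: pd.Series
    metric: str
    units: str = "degC"
    scenario: Optional[str] = None

    def __post_init__(self) -> None:
        if self.metric not in EXPOSURE_METRICS:
            raise ValueError(f"unknown exposure metric {self.metric!r}")
        if not isinstance(self.values.index, pd.DatetimeIndex):
            raise ValueError("exposure series needs a DatetimeIndex")
        if not self.values.index.is_monotonic_increasing:
            raise ValueError("exposure series index must be increasing")
        if self.metric != "hourly_mean":
            days = self.values.index.normalize()
            if days.duplicated().any():
                raise ValueError("daily series has more than one value per day")

    @property
    def is_daily(self) -> bool:
        return self.metric != "hourly_mean"

    def __len__(self) -> int:
        return len(self.values)
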