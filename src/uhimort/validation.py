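"""Model-versus-station evaluation.

Compares modelled temperature fields with hourly observations from two
station networks: official synoptic stations (typically outside dense
urban fabric, well calibrated) and crowdsourced personal weather stations
(PWS: dense in the city centre, noisier and individually biased).  Each
station is matched to the nearest grid cell by great-circle distance and
scored with mean bias, MAE, RMSE and temporal Pearson correlation; network
summaries average station metrics and add a spatial correlation of
station time-means against matched-cell time-means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import RegularGrid, TemperatureField

logger = logging.getLogger(__name__)

NETWORKS = ("official", "pws")

#: Stations with fewer paired hours than this are excluded from summaries.
MIN_PAIRED_HOURS = 24

EARTH_RADIUS_KM = 6371.0


@dataclass
class StationRecord:
    """One station: location, network and its hourly temperature series."""

    station_id: str
    lat: float
    lon: float
    network: str
    series: pd.Series  # hourly temperature, degC
    source_cell: Optional[tuple[int, int]] = None  # (iy, ix), synthetic truth

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise ValueError(f"network must be one of {NETWORKS}")


@dataclass
class StationMetrics:
    station_id: str
    network: str
    cell: tuple[int, int]
    bias: float       # mean(model - obs), degC
    mae: float
    rmse: float
    r: float          # temporal Pearson R; NaN when undefined
    r_defined: bool
    n: int
    obs_mean: float
    model_mean: float


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (vectorised over the second point)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def match_station_to_cell(station: StationRecord, grid: RegularGrid) -> tuple[int, int]:
    """Nearest cell centre by great-circle distance; ties to lowest (iy, ix)."""
    hx, hy = abs(grid.dx) / 2, abs(grid.dy) / 2
    if not (grid.x[0] - hx <= station.lon <= grid.x[-1] + hx
            and grid.y[0] - hy <= station.lat <= grid.y[-1] + hy):
        raise ValueError(
            f"station {station.station_id} at ({station.lat:.4f}, "
            f"{station.lon:.4f}) lies outside the grid bounds"
        )
    lon, lat = grid.cell_centres()
    d = haversine_km(station.lat, station.lon, lat.ravel(), lon.ravel())
    best = d.min()
    # ties broken deterministically: first index in row-major (y, x) order
    idx = int(np.flatnonzero(np.isclose(d, best, rtol=1e-12, atol=1e-12))[0])
    return divmod(idx, grid.shape[1])


def station_metrics(
    obs: pd.Series,
    model: pd.Series,
    station_id: str = "",
    network: str = "official",
    cell: tuple[int, int] = (0, 0),
    min_hours: int = MIN_PAIRED_HOURS,
) -> StationMetrics:
    """Paired-hour error statistics of a model series against observations.

    bias = mean(model - obs); MAE = mean|model - obs|;
    RMSE = sqrt(mean((model - obs)^2)); R = Pearson correlation.
    A constant series makes R undefined: it is reported as NaN with
    ``r_defined`` False, never silently zero.
    """
    idx = obs.dropna().index.intersection(model.dropna().index)
    if len(idx) < min_hours:
        raise ValueError(
            f"station {station_id or '?'}: only {len(idx)} paired hours "
            f"(minimum {min_hours})"
        )
    o = obs.reindex(idx).to_numpy(dtype=float)
    m = model.reindex(idx).to_numpy(dtype=float)
    resid = m - o
    r_defined = o.std() > 0 and m.std() > 0
    r = float(np.corrcoef(o, m)[0, 1]) if r_defined else float("nan")
    return StationMetrics(
        station_id=station_id, network=network, cell=cell,
        bias=float(resid.mean()),
        mae=float(np.abs(resid).mean()),
        rmse=float(np.sqrt((resid ** 2).mean())),
        r=r, r_defined=r_defined, n=len(idx),
        obs_mean=float(o.mean()), model_mean=float(m.mean()),
    )


def evaluate_stations(
    stations: Sequence[StationRecord],
    field: TemperatureField,
    min_hours: int = MIN_PAIRED_HOURS,
) -> pd.DataFrame:
    """Score every station against its matched cell in ``field``.

    Stations with too few paired hours are excluded and logged.  Returns
    one row per retained station.
    """
    grid = field.grid
    model_times = field.times
    rows = []
    for st in stations:
        iy, ix = match_station_to_cell(st, grid)
        model = pd.Series(field.values[:, iy, ix], index=model_times)
        try:
            m = station_metrics(st.series, model, station_id=st.station_id,
                                network=st.network, cell=(iy, ix),
                                min_hours=min_hours)
        except ValueError as exc:
            logger.info("excluding station: %s", exc)
            continue
        rows.append(vars(m))
    if not rows:
        raise ValueError("no station has enough paired hours")
    df = pd.DataFrame(rows)
    df["cell_iy"] = [c[0] for c in df.pop("cell")]
    return df


@dataclass
class ValidationStats:
    """Network x scenario summary of station metrics."""

    network: str
    scenario: str
    n_stations: int
    bias: float
    mae: float
    rmse: float
    r_temporal: float       # mean of defined per-station temporal R
    r_spatial: float        # Pearson R of station vs cell time-means; NaN if < 2 stations
    n_hours_mean: float

    def as_dict(self) -> dict:
        return vars(self).copy()


def network_summary(
    per_station: pd.DataFrame, network: str, scenario: str
) -> ValidationStats:
    """Unweighted mean of per-station metrics within one network."""
    grp = per_station[per_station["network"] == network]
    if grp.empty:
        raise ValueError(f"no stations in network {network!r}")
    defined = grp[grp["r_defined"]]
    if len(grp) >= 2 and grp["obs_mean"].std() > 0 and grp["model_mean"].std() > 0:
        r_spatial = float(np.corrcoef(grp["obs_mean"], grp["model_mean"])[0, 1])
    else:
        r_spatial = float("nan")
    return ValidationStats(
        network=network, scenario=scenario, n_stations=len(grp),
        bias=float(grp["bias"].mean()),
        mae=float(grp["mae"].mean()),
        rmse=float(grp["rmse"].mean()),
        r_temporal=float(defined["r"].mean()) if len(defined) else float("nan"),
        r_spatial=r_spatial,
        n_hours_mean=float(grp["n"].mean()),
    )
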