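"""Synthetic study-system generator.

Emulates the statistical structure of the real inputs so that every
downstream stage (exposure construction, attribution, validation) can be
exercised with known ground truth:

* two hourly gridded temperature scenarios over a ~16-day heatwave: a
  spatially uniform non-urban baseline (diurnal cycle plus a Gaussian
  heatwave pulse) and an urban field that adds an urban-heat-island
  surface decaying radially from the city centre, strongest at night and
  slightly negative by day (the counterfactual can be warmer than the
  urban run in daytime);
* a population grid concentrated toward the centre, so population
  weighting genuinely differs from an unweighted spatial mean;
* daily death counts per age stratum drawn from a Poisson model with a
  planted threshold log-linear temperature effect, together with the
  analytic expected attributable count for parameter-recovery checks;
* hourly pollutant concentrations positively coupled to temperature;
* two station networks sampling the fields: "official" stations near the
  grid edge with small noise, and personal weather stations in the centre
  with larger noise and per-station bias.

One global seed fans out into fixed per-component substreams, so adding a
generator never shifts the draws of an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box

from .grids import ExposureSeries, PopulationGrid, RegularGrid, TemperatureField
from .hia import AGE_GROUPS, ExposureResponse, MortalitySeries
from .validation import StationRecord

# substream indices of the fanned-out seed; append only, never reorder
_STREAM_UHII = 0
_STREAM_POPULATION = 1
_STREAM_MORTALITY = 2
_STREAM_POLLUTION = 3
_STREAM_STATIONS = 4

POLLUTANTS = ("ozone", "pm25")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system.

    Temperatures are degC, concentrations ug/m3, rates deaths/day.
    ``uhii_day_peak`` may be negative (daytime urban deficit); all other
    amplitudes must be non-negative.
    """

    grid_shape: tuple[int, int] = (25, 25)          # (ny, nx)
    cell_size: float = 0.02                          # degrees
    origin_lon: float = -0.45
    origin_lat: float = 51.30
    start: str = "2022-07-10"
    n_days: int = 16
    heatwave_peak_day: int = 9
    heatwave_width_days: float = 2.5
    base_daily_mean: float = 19.5
    diurnal_amplitude: float = 5.5
    heatwave_amplitude: float = 9.5
    uhii_night_peak: float = 5.8
    uhii_day_peak: float = -0.7
    uhii_heatwave_factor: float = 0.6   # UHII amplification at heatwave peak
    uhii_length_scale: float = 8.0      # cells
    noise_sd: float = 0.35
    population_total: float = 8.8e6
    population_length_scale: float = 5.0  # cells
    baseline_deaths_per_day: Mapping[str, float] = dc_field(
        default_factory=lambda: {"0-64": 26.0, "65-74": 20.0, "75plus": 72.0})
    planted_beta: Mapping[str, float] = dc_field(
        default_factory=lambda: {"0-64": 0.010, "65-74": 0.013, "75plus": 0.028})
    planted_threshold: float = 18.9
    beta_ci_fraction: float = 0.15      # relative halfwidth of the planted CI
    pollution_intercept: Mapping[str, float] = dc_field(
        default_factory=lambda: {"ozone": 30.0, "pm25": 4.0})
    pollution_temp_slope: Mapping[str, float] = dc_field(
        default_factory=lambda: {"ozone": 2.2, "pm25": 0.25})
    pollution_noise_sd: Mapping[str, float] = dc_field(
        default_factory=lambda: {"ozone": 6.0, "pm25": 1.2})
    n_official: int = 6
    n_pws: int = 24
    official_noise_sd: float = 0.4
    pws_noise_sd: float = 1.8
    pws_bias_sd: float = 0.8
    boundary_inset_cells: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.grid_shape
        if ny <= 0 or nx <= 0:
            raise ValueError("grid_shape must be positive in both dimensions")
        if self.n_days < 5:
            raise ValueError("n_days must be >= 5 (lag warm-up + 3 usable days)")
        for name in ("diurnal_amplitude", "heatwave_amplitude",
                     "uhii_night_peak", "noise_sd", "official_noise_sd",
                     "pws_noise_sd", "pws_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.baseline_deaths_per_day.values()):
            raise ValueError("baseline death rates must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(8)
        return np.random.default_rng(children[stream])

    def grid(self) -> RegularGrid:
        ny, nx = self.grid_shape
        x = self.origin_lon + self.cell_size * np.arange(nx)
        y = self.origin_lat + self.cell_size * np.arange(ny)
        return RegularGrid(x, y)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days * 24, freq="h")

    def planted_erf(self) -> ExposureResponse:
        """The planted heat ERF with symmetric relative CIs."""
        f = self.beta_ci_fraction
        return ExposureResponse(
            threshold=self.planted_threshold,
            coefficients={a: (b, b * (1 - f), b * (1 + f))
                          for a, b in self.planted_beta.items()},
        )


@dataclass
class GroundTruth:
    """Planted effect and analytic expected attributable deaths.

    ``expected_attributable`` maps a scenario label to per-stratum values
    of sum_d baseline_a * (exp(beta_a * max(0, X_d - T0)) - 1), the mean
    of the excess-death distribution under the planted Poisson model.
    """

    planted_beta: Mapping[str, float]
    planted_threshold: float
    expected_attributable: dict[str, dict[str, float]]

    def total(self, scenario: str) -> float:
        return sum(self.expected_attributable[scenario].values())


def _diurnal_shape(hours: np.ndarray) -> np.ndarray:
    """Smooth unit diurnal profile: minimum at 05:00, maximum at 15:00.

    Built from two half-sinusoids (a 10-hour rise, a 14-hour fall) so the
    asymmetric UK summer cycle is continuous and bounded in [-1, 1].
    """
    h = np.asarray(hours, dtype=float) % 24.0
    rising = (h >= 5.0) & (h < 15.0)
    out = np.empty_like(h)
    out[rising] = np.sin(np.pi * (h[rising] - 5.0) / 10.0 - np.pi / 2.0)
    fall = ~rising
    since_peak = (h[fall] - 15.0) % 24.0
    out[fall] = np.sin(np.pi / 2.0 + np.pi * since_peak / 14.0)
    return out


def _night_weight(hours: np.ndarray) -> np.ndarray:
    """Interpolation weight of the nighttime UHII amplitude.

    1 deep in the night (21:00-07:00), 0 deep in the day (09:00-19:00),
    with 2-hour linear ramps across the 08:00 and 20:00 day/night
    boundaries.
    """
    h = np.asarray(hours, dtype=float) % 24.0
    w = np.zeros_like(h)
    w[(h <= 7.0) | (h >= 21.0)] = 1.0
    ramp_down = (h > 7.0) & (h < 9.0)
    w[ramp_down] = (9.0 - h[ramp_down]) / 2.0
    ramp_up = (h > 19.0) & (h < 21.0)
    w[ramp_up] = (h[ramp_up] - 19.0) / 2.0
    return w


def _heatwave_pulse_norm(day_index: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    d = np.asarray(day_index, dtype=float)
    return np.exp(-((d - config.heatwave_peak_day) ** 2)
                  / (2.0 * config.heatwave_width_days ** 2))


def _radial_decay(config: SyntheticConfig) -> np.ndarray:
    ny, nx = config.grid_shape
    iy, ix = np.mgrid[0:ny, 0:nx]
    r2 = (iy - (ny - 1) / 2.0) ** 2 + (ix - (nx - 1) / 2.0) ** 2
    L = config.uhii_length_scale
    if not np.isfinite(L):
        return np.ones((ny, nx))
    return np.exp(-r2 / (2.0 * L ** 2))


def gen_temperature_grids(
    config: SyntheticConfig,
) -> tuple[TemperatureField, TemperatureField]:
    """Generate the urban and counterfactual non-urban hourly fields.

    The non-urban field is the deterministic regional background (diurnal
    cycle plus heatwave pulse, spatially uniform); the urban field adds
    the radially decaying UHII surface — its amplitude interpolates
    between the night and day peaks, is amplified near the heatwave peak —
    plus independent Gaussian noise.
    """
    grid = config.grid()
    times = config.times()
    hours = times.hour.to_numpy()
    day_idx = ((times - times[0]).days).to_numpy()

    background = (
        config.base_daily_mean
        + config.diurnal_amplitude * _diurnal_shape(hours)
        + config.heatwave_amplitude * _heatwave_pulse_norm(day_idx, config)
    )
    ny, nx = config.grid_shape
    non_urban_vals = np.broadcast_to(
        background[:, None, None], (len(times), ny, nx)
    ).copy()

    w = _night_weight(hours)
    amp = (config.uhii_day_peak
           + (config.uhii_night_peak - config.uhii_day_peak) * w)
    amp = amp * (1.0 + config.uhii_heatwave_factor
                 * _heatwave_pulse_norm(day_idx, config))
    uhii = amp[:, None, None] * _radial_decay(config)[None, :, :]
    if config.noise_sd > 0:
        uhii = uhii + config.rng(_STREAM_UHII).normal(
            0.0, config.noise_sd, size=uhii.shape)

    coords = {"time": times, "y": grid.y, "x": grid.x}
    dims = ("time", "y", "x")
    non_urban = TemperatureField(
        xr.DataArray(non_urban_vals, coords=coords, dims=dims, name="tas"),
        scenario="non-urban")
    urban = TemperatureField(
        xr.DataArray(non_urban_vals + uhii, coords=coords, dims=dims,
                     name="tas"),
        scenario="urban")
    return urban, non_urban


def gen_population_grid(
    config: SyntheticConfig, profile: str = "gaussian"
) -> PopulationGrid:
    """Population counts on the model grid.

    ``gaussian`` (default): a radial profile centred on the grid centre
    with multiplicative lognormal heterogeneity, scaled to the configured
    total.  ``uniform`` and ``point`` profiles exist for tests.
    """
    grid = config.grid()
    ny, nx = config.grid_shape
    if profile == "uniform":
        counts = np.full((ny, nx), config.population_total / (ny * nx))
    elif profile == "point":
        counts = np.zeros((ny, nx))
        counts[(ny - 1) // 2, (nx - 1) // 2] = config.population_total
    elif profile == "gaussian":
        iy, ix = np.mgrid[0:ny, 0:nx]
        r2 = (iy - (ny - 1) / 2.0) ** 2 + (ix - (nx - 1) / 2.0) ** 2
        shape = np.exp(-r2 / (2.0 * config.population_length_scale ** 2))
        jitter = config.rng(_STREAM_POPULATION).lognormal(
            0.0, 0.3, size=(ny, nx))
        counts = shape * jitter
        counts *= config.population_total / counts.sum()
    else:
        raise ValueError(f"unknown population profile {profile!r}")
    return PopulationGrid(counts, grid)


def expected_attributable(
    exposure: ExposureSeries, config: SyntheticConfig
) -> dict[str, float]:
    """Analytic expected attributable deaths per stratum for one exposure.

    Under the planted model the expected excess on day d in stratum a is
    baseline_a * (exp(beta_a * max(0, X_d - T0)) - 1); summing over days
    gives the quantity attribution should recover on average.
    """
    excess = np.maximum(
        0.0, exposure.values.to_numpy() - config.planted_threshold)
    out = {}
    for stratum, baseline in config.baseline_deaths_per_day.items():
        beta = config.planted_beta[stratum]
        out[stratum] = float(baseline * (np.exp(beta * excess) - 1.0).sum())
    return out


def gen_mortality(
    exposure: ExposureSeries, config: SyntheticConfig
) -> tuple[MortalitySeries, GroundTruth]:
    """Draw daily death counts with the planted temperature effect.

    ``exposure`` must be the daily (lagged-mean) series the ERF will later
    consume; deaths_{d,a} ~ Poisson(baseline_a * RR_a(X_d)).
    """
    if not exposure.is_daily:
        raise ValueError("mortality generation expects a daily exposure series")
    x = exposure.values
    gaps = pd.date_range(x.index[0], x.index[-1], freq="D").difference(x.index)
    if len(gaps):
        raise ValueError("exposure series has gaps")
    rng = config.rng(_STREAM_MORTALITY)
    excess = np.maximum(0.0, x.to_numpy() - config.planted_threshold)
    cols = {}
    for stratum, baseline in config.baseline_deaths_per_day.items():
        mu = baseline * np.exp(config.planted_beta[stratum] * excess)
        cols[stratum] = rng.poisson(mu)
    deaths = pd.DataFrame(cols, index=x.index)
    scen = exposure.scenario or "urban"
    truth = GroundTruth(
        planted_beta=dict(config.planted_beta),
        planted_threshold=config.planted_threshold,
        expected_attributable={scen: expected_attributable(exposure, config)},
    )
    return MortalitySeries(deaths), truth


def gen_pollution(
    temperature: ExposureSeries, config: SyntheticConfig
) -> pd.DataFrame:
    """Hourly pollutant concentrations coupled to temperature.

    concentration = intercept + slope * T + noise, floored at zero, so
    hotter days carry higher ozone and PM2.5 — the qualitative pattern of
    urban background monitoring during heat episodes.
    """
    rng = config.rng(_STREAM_POLLUTION)
    t = temperature.values.to_numpy()
    out = {}
    for pollutant in POLLUTANTS:
        conc = (config.pollution_intercept[pollutant]
                + config.pollution_temp_slope[pollutant] * t)
        sd = config.pollution_noise_sd[pollutant]
        if sd > 0:
            conc = conc + rng.normal(0.0, sd, size=conc.shape)
        out[pollutant] = np.maximum(conc, 0.0)
    return pd.DataFrame(out, index=temperature.values.index)


@dataclass
class StationTruth:
    """Bookkeeping of how a synthetic station perturbs its source cell."""

    source_cell: tuple[int, int]
    bias: float
    perturbation: pd.Series  # bias + noise actually added, per hour


def gen_stations(
    urban: TemperatureField,
    non_urban: TemperatureField,
    config: SyntheticConfig,
) -> tuple[list[StationRecord], dict[str, StationTruth]]:
    """Sample the two station networks from the gridded fields.

    Official stations sit on the outermost cell ring and observe the
    non-urban-like environment with small unbiased noise; personal
    weather stations sit in the central quarter of the grid, observe the
    urban field, and carry larger noise plus a fixed per-station bias.
    Station coordinates are jittered within their source cell, so
    nearest-cell matching recovers the true cell.
    """
    if not urban.grid.same_as(non_urban.grid):
        raise ValueError("scenario fields are on different grids")
    grid = urban.grid
    ny, nx = grid.shape
    ring = [(iy, ix) for iy in range(ny) for ix in range(nx)
            if iy in (0, ny - 1) or ix in (0, nx - 1)]
    radius = max(2.0, min(ny, nx) / 4.0)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    central = [(iy, ix) for iy in range(ny) for ix in range(nx)
               if (iy - cy) ** 2 + (ix - cx) ** 2 <= radius ** 2]
    if config.n_official > len(ring):
        raise ValueError(
            f"requested {config.n_official} official stations but only "
            f"{len(ring)} edge cells exist")
    if config.n_pws > len(central):
        raise ValueError(
            f"requested {config.n_pws} PWS but only {len(central)} central "
            "cells exist")

    rng = config.rng(_STREAM_STATIONS)
    times = urban.times
    stations: list[StationRecord] = []
    truths: dict[str, StationTruth] = {}

    def _place(cells, count, network, field, noise_sd, bias_sd):
        chosen = [cells[i] for i in rng.choice(len(cells), size=count,
                                               replace=False)]
        for k, (iy, ix) in enumerate(chosen):
            sid = f"{network}-{k:03d}"
            bias = float(rng.normal(0.0, bias_sd)) if bias_sd > 0 else 0.0
            noise = (rng.normal(0.0, noise_sd, size=len(times))
                     if noise_sd > 0 else np.zeros(len(times)))
            perturb = pd.Series(bias + noise, index=times)
            series = pd.Series(field.values[:, iy, ix], index=times) + perturb
            jlon = float(rng.uniform(-0.25, 0.25)) * grid.dx
            jlat = float(rng.uniform(-0.25, 0.25)) * grid.dy
            stations.append(StationRecord(
                station_id=sid, lat=float(grid.y[iy] + jlat),
                lon=float(grid.x[ix] + jlon), network=network,
                series=series, source_cell=(iy, ix)))
            truths[sid] = StationTruth((iy, ix), bias, perturb)

    _place(ring, config.n_official, "official", non_urban,
           config.official_noise_sd, 0.0)
    _place(central, config.n_pws, "pws", urban,
           config.pws_noise_sd, config.pws_bias_sd)
    return stations, truths


def region_boundary(config: SyntheticConfig):
    """Rectangular analysis boundary inset from the grid edge."""
    grid = config.grid()
    k = config.boundary_inset_cells
    ny, nx = grid.shape
    if 2 * k >= min(ny, nx):
        raise ValueError("boundary inset leaves no cells")
    hx, hy = grid.dx / 2.0, grid.dy / 2.0
    return box(grid.x[k] - hx, grid.y[k] - hy,
               grid.x[nx - 1 - k] + hx, grid.y[ny - 1 - k] + hy)
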