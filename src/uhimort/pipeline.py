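"""End-to-end pipeline: simulate, ingest, analyse, report.

``simulate`` writes a complete synthetic input bundle to disk in the same
formats the ingestion readers accept.  ``run_pipeline`` loads a
:class:`RunConfig`, chains exposure construction, heat / urban-heat-island /
pollutant attribution and station validation, and writes the report
bundle.  ``analyse`` is the in-memory core both paths share.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import xarray as xr
import yaml
from shapely.geometry.base import BaseGeometry

from . import io as uio
from . import report as urep
from . import synthetic as usyn
from .exposure import (
    daily_aggregate,
    daily_max_8h_running_mean,
    lag_mean,
    make_region_mask,
    population_weighted_series,
    regrid_conservative,
    uhii_stats,
)
from .grids import PopulationGrid, TemperatureField
from .hia import (
    AttributionResult,
    ExposureResponse,
    MortalitySeries,
    PollutantCoefficient,
    attribute_heat,
    attribute_pollutant,
    attribute_uhi,
)
from .validation import StationRecord, evaluate_stations, network_summary

logger = logging.getLogger(__name__)

# COMEAP-style all-cause coefficients, percent per 10 ug/m3 with 95% CI
DEFAULT_POLLUTANT_COEFFICIENTS = {
    "ozone": PollutantCoefficient("ozone", 0.34, 0.12, 0.56),
    "pm25": PollutantCoefficient("pm25", 1.04, 0.52, 1.56),
}


@dataclass
class RunConfig:
    """Paths, analysis period and exposure-response configuration."""

    grid_urban: Path
    grid_non_urban: Path
    population: Path
    boundary: Path
    mortality: Path
    pollution: Path
    stations: Path
    out_dir: Path
    period_start: Optional[str] = None
    period_end: Optional[str] = None
    erf: Optional[ExposureResponse] = None
    pollutant_coefficients: Mapping[str, PollutantCoefficient] = field(
        default_factory=lambda: dict(DEFAULT_POLLUTANT_COEFFICIENTS))
    pollutant_linear: bool = False
    seed: int = 0

    @property
    def period(self) -> Optional[tuple[str, str]]:
        if self.period_start is None or self.period_end is None:
            return None
        if pd.Timestamp(self.period_start) > pd.Timestamp(self.period_end):
            raise ValueError("period start is after period end")
        return (self.period_start, self.period_end)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def _p(key):  # paths in the file are relative to the file
            return (base / raw["paths"][key]).resolve()
        erf = None
        if "erf" in raw:
            block = raw["erf"]
            erf = ExposureResponse(
                threshold=float(block["threshold_C"]),
                coefficients={
                    s: (float(v["central"]), float(v["low"]), float(v["high"]))
                    for s, v in block["strata"].items()},
            )
        coeffs = dict(DEFAULT_POLLUTANT_COEFFICIENTS)
        for name, v in raw.get("pollutant_coefficients", {}).items():
            coeffs[name] = PollutantCoefficient(
                name, float(v["central"]), float(v["low"]), float(v["high"]))
        period = raw.get("period", {})
        return cls(
            grid_urban=_p("grid_urban"), grid_non_urban=_p("grid_non_urban"),
            population=_p("population"), boundary=_p("boundary"),
            mortality=_p("mortality"), pollution=_p("pollution"),
            stations=_p("stations"),
            out_dir=(base / raw["out_dir"]).resolve(),
            period_start=period.get("start"), period_end=period.get("end"),
            erf=erf, pollutant_coefficients=coeffs,
            pollutant_linear=bool(raw.get("pollutant_linear", False)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class AnalysisInputs:
    """Everything the in-memory analysis needs, format-free."""

    urban: TemperatureField
    non_urban: TemperatureField
    population: PopulationGrid
    boundary: BaseGeometry
    mortality: MortalitySeries
    pollution: pd.DataFrame
    stations: Sequence[StationRecord]
    erf: ExposureResponse
    pollutant_coefficients: Mapping[str, PollutantCoefficient]
    period: Optional[tuple] = None
    pollutant_linear: bool = False


@dataclass
class AnalysisResults:
    exposures: dict
    uhii: object
    heat: dict[str, AttributionResult]
    pollutants: dict[str, AttributionResult]
    validation: pd.DataFrame
    validation_summaries: list
    mortality: MortalitySeries


def analyse(inputs: AnalysisInputs) -> AnalysisResults:
    """Exposure -> attribution (urban, non-urban, UHI) -> pollutants -> validation."""
    pop = inputs.population
    if not pop.grid.same_as(inputs.urban.grid):
        pop = regrid_conservative(pop, inputs.urban.grid)
    mask = make_region_mask(inputs.boundary, inputs.urban.grid)

    exposures: dict = {}
    lagged: dict = {}
    for fld in (inputs.urban, inputs.non_urban):
        hourly = population_weighted_series(fld, pop, mask)
        daily = daily_aggregate(hourly, "mean")
        lag = lag_mean(daily)
        exposures[fld.scenario] = {"hourly": hourly, "daily": daily,
                                   "lag012": lag}
        lagged[fld.scenario] = lag

    uhii = uhii_stats(exposures["urban"]["hourly"],
                      exposures["non-urban"]["hourly"],
                      inputs.urban, inputs.non_urban)

    heat = {}
    for scen in ("urban", "non-urban"):
        heat[scen] = attribute_heat(lagged[scen], inputs.mortality,
                                    inputs.erf, period=inputs.period,
                                    scenario=scen)
    heat["uhi"] = attribute_uhi(heat["urban"], heat["non-urban"])

    pollutants = {}
    for name, coeff in inputs.pollutant_coefficients.items():
        if name not in inputs.pollution.columns:
            logger.info("pollutant %s not in concentration data; skipped", name)
            continue
        metric = daily_max_8h_running_mean(inputs.pollution[name])
        pollutants[name] = attribute_pollutant(
            metric, inputs.mortality, coeff,
            period=(str(heat["urban"].period[0].date()),
                    str(heat["urban"].period[1].date())),
            linear=inputs.pollutant_linear)
        exposures[name] = {"daily_max_8h_mean": metric}

    per_station = evaluate_stations(inputs.stations, inputs.urban)
    per_station_nu = evaluate_stations(inputs.stations, inputs.non_urban)
    summaries = []
    for scen, df in (("urban", per_station), ("non-urban", per_station_nu)):
        for network in sorted(set(df["network"])):
            summaries.append(network_summary(df, network, scen))
    per_station["scenario"] = "urban"
    per_station_nu["scenario"] = "non-urban"
    validation = pd.concat([per_station, per_station_nu], ignore_index=True)

    return AnalysisResults(
        exposures=exposures, uhii=uhii, heat=heat, pollutants=pollutants,
        validation=validation, validation_summaries=summaries,
        mortality=inputs.mortality)


# -- synthetic bundle --------------------------------------------------------

@dataclass
class SyntheticBundle:
    """In-memory synthetic dataset plus its ground truth."""

    config: usyn.SyntheticConfig
    inputs: AnalysisInputs
    ground_truth: usyn.GroundTruth
    station_truths: dict


def build_synthetic(config: usyn.SyntheticConfig) -> SyntheticBundle:
    """Generate a full synthetic study system.

    Mortality is drawn from the urban-scenario exposure (people live in
    the real, urbanised city); the ground truth carries the analytic
    expected attributable deaths for both scenarios.
    """
    urban, non_urban = usyn.gen_temperature_grids(config)
    pop = usyn.gen_population_grid(config)
    boundary = usyn.region_boundary(config)
    mask = make_region_mask(boundary, urban.grid)

    hourly_u = population_weighted_series(urban, pop, mask)
    hourly_n = population_weighted_series(non_urban, pop, mask)
    lag_u = lag_mean(daily_aggregate(hourly_u, "mean"))
    lag_n = lag_mean(daily_aggregate(hourly_n, "mean"))

    mortality, truth = usyn.gen_mortality(lag_u, config)
    truth.expected_attributable["non-urban"] = usyn.expected_attributable(
        lag_n, config)
    pollution = usyn.gen_pollution(hourly_u, config)
    stations, station_truths = usyn.gen_stations(urban, non_urban, config)

    inputs = AnalysisInputs(
        urban=urban, non_urban=non_urban, population=pop, boundary=boundary,
        mortality=mortality, pollution=pollution, stations=stations,
        erf=config.planted_erf(),
        pollutant_coefficients=dict(DEFAULT_POLLUTANT_COEFFICIENTS),
    )
    return SyntheticBundle(config=config, inputs=inputs, ground_truth=truth,
                           station_truths=station_truths)


def simulate(config: usyn.SyntheticConfig, out_dir) -> dict:
    """Write the synthetic input bundle to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = build_synthetic(config)
    inp = bundle.inputs
    paths = {
        "grid_urban": out / "temperature_urban.nc",
        "grid_non_urban": out / "temperature_non_urban.nc",
        "population": out / "population.nc",
        "boundary": out / "boundary.geojson",
        "mortality": out / "mortality.csv",
        "pollution": out / "pollution.csv",
        "stations": out / "stations.csv",
    }
    uio.write_gridded(inp.urban, paths["grid_urban"])
    uio.write_gridded(inp.non_urban, paths["grid_non_urban"])
    uio.write_population(inp.population, paths["population"])
    uio.write_boundary(inp.boundary, paths["boundary"])
    uio.write_mortality(inp.mortality, paths["mortality"])
    uio.write_pollution(inp.pollution, paths["pollution"])
    uio.write_stations(inp.stations, paths["stations"])
    truth_path = out / "ground_truth.json"
    urep.write_json({
        "planted_beta": dict(bundle.ground_truth.planted_beta),
        "planted_threshold": bundle.ground_truth.planted_threshold,
        "expected_attributable": bundle.ground_truth.expected_attributable,
    }, truth_path)
    paths["ground_truth"] = truth_path
    return {k: str(v) for k, v in paths.items()}


def load_inputs(config: RunConfig) -> AnalysisInputs:
    """Read every input referenced by the run configuration."""
    erf = config.erf
    if erf is None:
        raise ValueError("run configuration has no exposure-response block")
    return AnalysisInputs(
        urban=uio.read_gridded(config.grid_urban, scenario="urban"),
        non_urban=uio.read_gridded(config.grid_non_urban,
                                   scenario="non-urban"),
        population=uio.read_population(config.population),
        boundary=uio.read_boundary(config.boundary),
        mortality=uio.read_mortality(config.mortality),
        pollution=uio.read_pollution(config.pollution),
        stations=uio.read_stations(config.stations),
        erf=erf,
        pollutant_coefficients=config.pollutant_coefficients,
        period=config.period,
        pollutant_linear=config.pollutant_linear,
    )


def write_reports(results: AnalysisResults, out_dir) -> dict:
    """Write the report bundle; returns row counts per artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, res in {**results.heat, **results.pollutants}.items():
        fname = f"attribution_{name.replace('-', '_')}.csv"
        urep.write_attribution_csv(res, out / fname)
        counts[fname] = len(res.daily)

    table = urep.scenario_totals_table(
        results.heat["urban"], results.heat["non-urban"],
        results.heat["uhi"], results.mortality)
    table.rename_axis("scenario").to_csv(out / "totals_table.csv")
    counts["totals_table.csv"] = len(table)

    urep.write_json(urep.totals_json(
        results.heat["urban"], results.heat["non-urban"],
        results.heat["uhi"], results.mortality,
        pollutants=results.pollutants), out / "totals.json")

    frac = urep.daily_fraction_table({**results.heat, **results.pollutants})
    frac.to_csv(out / "daily_attributable_fraction.csv",
                date_format="%Y-%m-%d", float_format="%.10g")
    counts["daily_attributable_fraction.csv"] = len(frac)

    pd.DataFrame([results.uhii.as_dict()]).to_csv(
        out / "uhii_summary.csv", index=False, float_format="%.10g")
    if results.uhii.map_all is not None:
        xr.Dataset({
            "uhii_all": results.uhii.map_all,
            "uhii_day": results.uhii.map_day,
            "uhii_night": results.uhii.map_night,
        }).to_netcdf(out / "uhii_maps.nc", engine="scipy")

    vtab = urep.validation_table(results.validation_summaries)
    vtab.to_csv(out / "validation_report.csv", index=False,
                float_format="%.10g")
    counts["validation_report.csv"] = len(vtab)
    results.validation.to_csv(out / "validation_stations.csv", index=False,
                              float_format="%.10g")
    return counts


def run_pipeline(config: RunConfig) -> AnalysisResults:
    """Load inputs, run the full analysis, write the report bundle."""
    inputs = load_inputs(config)
    results = analyse(inputs)
    counts = write_reports(results, config.out_dir)
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in dataclasses.asdict(config).items()
                        if k not in ("erf", "out_dir")},
                       sort_keys=True, default=str).encode()
        ).hexdigest(),
        "row_counts": counts,
    }
    urep.write_json(manifest, Path(config.out_dir) / "run_manifest.json")
    return results
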