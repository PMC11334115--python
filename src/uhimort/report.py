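"""Report layer: rounded tables and machine-readable totals.

Internal attribution values carry full precision; rounding (half-to-even,
integers for heat deaths, one decimal for pollutant deaths) happens only
here.  In the scenario totals table the total column is the sum of the
rounded age-stratum entries and the urban-heat-island row is differenced
before rounding, so the printed arithmetic is internally consistent by
construction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .hia import ALL_AGES, QUANTILES, AttributionResult, MortalitySeries
from .validation import ValidationStats

SCENARIO_ROWS = ("Urban", "Non-urban", "UHI")


def round_half_even(x: float, ndigits: int = 0) -> float:
    """Banker's rounding; returns an int when ndigits == 0."""
    r = round(float(x), ndigits)
    return int(r) if ndigits == 0 else r


def percent_of(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """100 * numerator / denominator, rounded half-to-even."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    return round_half_even(100.0 * numerator / denominator, ndigits)


def ratio_of(numerator: float, denominator: float, ndigits: int = 0) -> float:
    if denominator == 0:
        raise ValueError("ratio with zero denominator")
    return round_half_even(numerator / denominator, ndigits)


def _rounded_row(totals: pd.DataFrame, strata: Sequence[str],
                 ndigits: int = 0) -> dict:
    """Round per-stratum entries; the total is the sum of rounded entries."""
    row = {}
    for q in QUANTILES:
        vals = {s: round_half_even(totals.loc[s, q], ndigits) for s in strata}
        vals["total"] = round_half_even(sum(vals.values()), ndigits)
        row[q] = vals
    return row


def scenario_totals_table(
    urban: AttributionResult,
    non_urban: AttributionResult,
    uhi: AttributionResult,
    mortality: MortalitySeries,
    ndigits: int = 0,
) -> pd.DataFrame:
    """Heat-attribution totals by scenario and age group, with intervals.

    Rows Urban / Non-urban / UHI / Total mortality; columns total plus the
    age strata.  Attribution entries are formatted ``central (low-high)``.
    """
    strata = list(urban.strata)
    period = pd.date_range(urban.period[0], urban.period[1], freq="D")
    rows = {}
    for name, res in zip(SCENARIO_ROWS, (urban, non_urban, uhi)):
        rows[name] = _rounded_row(res.totals(), strata, ndigits)
    deaths = mortality.deaths.loc[period]
    out = pd.DataFrame(index=list(SCENARIO_ROWS) + ["Total mortality"],
                       columns=["total"] + strata, dtype=object)
    for name in SCENARIO_ROWS:
        r = rows[name]
        for col in out.columns:
            out.loc[name, col] = (
                f"{r['central'][col]} ({r['low'][col]}-{r['high'][col]})")
    for s in strata:
        out.loc["Total mortality", s] = round_half_even(deaths[s].sum(), ndigits)
    out.loc["Total mortality", "total"] = sum(
        out.loc["Total mortality", s] for s in strata)
    return out


def totals_json(
    urban: AttributionResult,
    non_urban: AttributionResult,
    uhi: AttributionResult,
    mortality: MortalitySeries,
    pollutants: Optional[Mapping[str, AttributionResult]] = None,
) -> dict:
    """Machine-readable twin of the totals table (full precision)."""
    strata = list(urban.strata)
    period = pd.date_range(urban.period[0], urban.period[1], freq="D")
    deaths = mortality.deaths.loc[period]
    out = {
        "period": [str(urban.period[0].date()), str(urban.period[1].date())],
        "total_mortality": {s: float(deaths[s].sum()) for s in strata}
        | {"total": float(deaths.to_numpy().sum())},
        "heat": {},
        "pollutants": {},
    }
    for name, res in (("urban", urban), ("non_urban", non_urban),
                      ("uhi", uhi)):
        t = res.totals()
        out["heat"][name] = {
            s: {q: float(t.loc[s, q]) for q in QUANTILES}
            for s in list(strata) + [ALL_AGES]
        }
    for pname, res in (pollutants or {}).items():
        t = res.totals()
        out["pollutants"][pname] = {
            q: float(t.loc[ALL_AGES, q]) for q in QUANTILES}
    return out


def daily_fraction_table(
    results: Mapping[str, AttributionResult], quantile: str = "central"
) -> pd.DataFrame:
    """Daily attributable fraction per exposure, one column per result."""
    cols = {name: res.daily_fraction(quantile) for name, res in results.items()}
    df = pd.DataFrame(cols)
    df.index.name = "date"
    return df


def validation_table(summaries: Sequence[ValidationStats]) -> pd.DataFrame:
    """Network x scenario validation metrics, one row per combination."""
    df = pd.DataFrame([s.as_dict() for s in summaries])
    return df.sort_values(["network", "scenario"], kind="stable").reset_index(
        drop=True)


def write_attribution_csv(result: AttributionResult, path) -> None:
    df = result.daily.copy()
    df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.10g")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
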