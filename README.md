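# uhimort

Counterfactual health impact assessment of urban heat: how many deaths
during a city heatwave are attributable to heat, and how many of those to
the urban heat island (UHI)?

The package is aimed at environmental-epidemiology and urban-climate
researchers who have (or can simulate) hourly gridded 2-m air temperature
for two scenarios — the real urbanised city and a counterfactual in which
urban land surfaces are replaced by vegetation — together with a
population grid, a region boundary, daily mortality counts by age group,
and monitored pollutant concentrations. It chains exposure construction,
attribution and validation into one tested pipeline, and ships a
synthetic-data generator with known ground truth so the whole analysis
runs end to end without any external data.

## Model

Regional exposure is the population-weighted mean temperature over cells
inside the boundary,

    X(t) = Σᵢ wᵢ Tᵢ(t) / Σᵢ wᵢ,

aggregated to daily means and then to the 0–2 day lag mean
X_d = (X_d + X_{d−1} + X_{d−2})/3. Risk follows a threshold log-linear
exposure–response function per age stratum a:

    RR_a(X_d) = exp(β_a · max(0, X_d − T₀)),   T₀ = 18.9 °C by default.

The attributable fraction is AF = (RR − 1)/RR and the attributable number
on day d is AF · M_{d,a} with M the observed death count; totals sum over
days and strata. The same attribution is run with the urban and the
non-urban temperature series, and **UHI-attributable mortality is the
paired difference** of the two results, quantile by quantile, so the
confidence interval (propagated from the coefficient CI only) reflects
identical coefficient uncertainty in both scenarios.

Pollutant attribution (ozone, PM2.5) uses the daily maximum 8-hour
running mean concentration C_d with a coefficient quoted as p% per
10 µg m⁻³, read log-linearly: RR_d = (1 + p/100)^(C_d/10), threshold
zero, all-ages mortality. Model skill against station observations
(official network and personal weather stations) is summarised with mean
bias, MAE, RMSE and Pearson correlation per network × scenario.

## Worked example

```python
from uhimort import SyntheticConfig, build_synthetic
from uhimort.pipeline import analyse
from uhimort.report import scenario_totals_table

bundle = build_synthetic(SyntheticConfig(seed=1))   # ~16-day heatwave
res = analyse(bundle.inputs)
print(scenario_totals_table(res.heat["urban"], res.heat["non-urban"],
                            res.heat["uhi"], res.mortality))
```

prints

```
                         total        0-64       65-74         75plus
Urban            276 (238-313)  27 (23-31)  28 (24-32)  221 (191-250)
Non-urban        192 (165-218)  19 (16-21)  19 (16-22)  154 (133-175)
UHI                 85 (72-95)    9 (7-10)    9 (7-10)     67 (58-75)
Total mortality           1874         385         302           1187
```

Of 1874 synthetic deaths in the 14-day analysis period, 276 (95% CI
238–313) are attributed to heat under the urban scenario and 192 under
the counterfactual; the difference, 85 deaths (30% of the heat burden,
differenced before rounding), is attributed to the urban heat island — most of it in the
oldest stratum. The generator's analytic expectation for the urban
scenario is 284.3 deaths, so the estimate sits where the planted effect
says it should. The same run gives a population-weighted hourly UHI
intensity of min −0.9 / mean 2.3 / max 6.9 °C and pollutant burdens of
59.8 (21.4–97.4) deaths for ozone and 22.1 (11.1–33.0) for PM2.5.

A file-based run of the same pipeline:

```sh
uhimort simulate --seed 1 --out data/        # writes NetCDF/CSV/GeoJSON inputs
uhimort all --config run.yaml                # exposure → attribution → reports
```

`uhimort all` writes per-day attribution CSVs, a scenario totals table,
daily attributable-fraction series, UHI-intensity summary and maps, a
validation report, and a machine-readable `totals.json`.

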