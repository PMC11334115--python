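# Methods

## Attribution model

Heat-mortality risk is a threshold log-linear exposure–response function
(ERF) on the 0–2 day lag mean of regional population-weighted daily mean
temperature. For stratum *a* and day *d*:

* RR_a(X_d) = exp(β_a · max(0, X_d − T₀)); RR = 1 at or below the
  threshold T₀ (default 18.9 °C, configurable).
* AF = (RR − 1)/RR. The RR − 1 approximation is deliberately not used:
  (RR − 1)/RR is the standard attributable-fraction definition and is
  exact for the counting argument "share of observed deaths in excess of
  the baseline rate".
* Attributable number AD_{d,a} = AF · M_{d,a} with M the *observed*
  death count. Totals are plain sums over days and strata, so additivity
  holds exactly.

Confidence intervals are propagated from the coefficient CI only: the
low/central/high slope is pushed through the whole calculation, giving a
low/central/high attributable total. No sampling uncertainty of the
death counts is modelled — intervals mean "uncertainty in the ERF", as
is conventional for this style of assessment.

**UHI attribution.** The urban heat island contribution is the paired
difference of the urban and counterfactual non-urban attribution,
computed per (day, stratum, quantile) *before* any summation or
rounding. Pairing the same coefficient quantile in both scenarios makes
the UHI interval narrower than independent differencing would — the
coefficient error is common to both scenarios and largely cancels in the
difference, which is the correct behaviour when the only modelled
uncertainty is the shared ERF. No further covariance modelling is
attempted.

**Pollutants.** Coefficients quoted as "p% per 10 µg m⁻³" (defaults:
ozone 0.34% [0.12–0.56], PM2.5 1.04% [0.52–1.56]) are read
log-linearly, RR = (1 + p/100)^(C/10), with threshold 0 and the daily
maximum 8-hour running mean as the exposure metric. A linear option
(RR = 1 + p/100 · C/10) sits behind a flag; at urban background
concentrations the two differ by well under 1% of the attributable
number. Pollutants are assumed to affect all ages equally, so the
all-ages death count is used with a single stratum.

**ERF fitting.** `fit_erf` is a Poisson GLM (log link, fitted with
statsmodels) of daily deaths on max(0, X_d − T₀) with an intercept, per
stratum; the Wald 95% CI comes from the observed information. It exists
for parameter recovery against data with a planted slope, not to replace
externally derived coefficients in a real assessment. At least 30 paired
days and at least one above-threshold day are required; with no
above-threshold days the slope is unidentifiable and the fit refuses.

## Exposure operators

* **Conservative regridding** treats population as an extensive
  quantity: each source count is split across target cells in proportion
  to polygon overlap area (shapely geometry), so totals are conserved to
  1e−9 relative whenever the target covers the sources. Population is
  never averaged as a density.
* **Region mask**: a cell belongs to the region iff its centre lies in
  the boundary polygon. Binary membership keeps the mask testable;
  area-fraction weighting is out of scope.
* **Day boundary** is the local civil clock of the input timestamps; a
  daily aggregate needs ≥ 75% of hours (18 of 24), incomplete days are
  dropped and logged.
* **Lag mean** requires all three days of the window; the first two days
  of a record are excluded rather than padded, preventing silent
  exposure dilution at the edges.
* **8-hour running means** are labelled by their ending hour and
  attributed to the day containing it; a window is valid with ≥ 6 of 8
  hours, a day needs ≥ 18 valid windows. These completeness rules follow
  standard air-quality reporting practice.
* Population weighting and daily averaging commute for the mean (both
  are linear); the test suite asserts this, so either order is valid.

## Synthetic study system

The generator emulates the statistical structure of a July heatwave in a
large city (defaults sized like Greater London) with known ground truth:

* **Fields**: 25 × 25 cells of 0.02°, 16 days hourly. The non-urban
  scenario is a smooth background: an asymmetric diurnal cycle (minimum
  05:00, maximum 15:00, built from two half-sinusoids) around a 19.5 °C
  daily mean with amplitude 5.5 °C, plus a Gaussian heatwave pulse
  (peak +9.5 °C on day 9, width 2.5 days). The urban scenario adds a UHI
  surface: a Gaussian radial profile from the grid centre (length scale
  8 cells) whose amplitude interpolates between a nighttime peak
  (5.8 °C) and a small negative daytime value (−0.7 °C, the
  counterfactual can run warmer by day), is amplified by up to 60% at
  the heatwave peak, plus N(0, 0.35²) noise. Night is 20:00–08:00 with
  2-hour ramps at the boundaries. With these defaults the
  population-weighted hourly urban–non-urban difference comes out near
  min −0.9 / mean 2.3 / max 6.9 °C — nocturnal, centre-loaded, and of
  the magnitude observed for a severe UK heatwave.
* **Population**: Gaussian radial profile (length scale 5 cells) with
  lognormal heterogeneity, scaled to 8.8 million; uniform and point-mass
  profiles exist so tests can separate weighting from masking.
* **Mortality**: deaths_{d,a} ~ Poisson(baseline_a · exp(β_a ·
  max(0, X_d − 18.9))) driven by the urban lagged exposure (people live
  in the urbanised city; the counterfactual only enters attribution).
  Baselines 26/20/72 deaths day⁻¹ and slopes 0.010/0.013/0.028 °C⁻¹ for
  ages 0–64 / 65–74 / ≥75 — heat risk concentrated in the oldest
  stratum, total ~118 deaths day⁻¹ as for a city of this size. The
  planted slopes are design choices of the generator, not published
  coefficients. The ground truth records the analytic expectation
  Σ_d baseline_a (e^{β_a Δ_d} − 1) per scenario; the attribution
  estimator is unbiased for it, which the acceptance suite checks with a
  3-standard-error Monte-Carlo envelope over 20 seeds.
* **Pollutants**: hourly concentration = intercept + slope · T(t) +
  noise, floored at 0 (ozone 30 + 2.2 T; PM2.5 4 + 0.25 T), giving hot-day
  daily-max-8h means near 100 and 12 µg m⁻³ respectively — plausible
  urban background levels for a recent heatwave.
* **Stations**: official stations sample the outermost cell ring from
  the non-urban field with N(0, 0.4²) noise and no bias; personal
  weather stations sample the central quarter of the urban field with
  N(0, 1.8²) noise plus a fixed per-station N(0, 0.8²) bias.
  Coordinates are jittered within the source cell so nearest-cell
  matching provably recovers it. Each station's exact perturbation
  series is retained, making error metrics checkable against
  bookkeeping rather than against themselves.
* **Seeding**: one global seed spawns fixed per-component substreams
  (UHI noise, population, mortality, pollution, stations); adding a
  generator appends a stream and never shifts existing draws. Same seed
  ⇒ bit-identical outputs.

What the generator does *not* emulate: synoptic weather variability and
advection, spatial correlation of the noise, within-city heterogeneity
of the temperature–mortality relationship, harvesting/mortality
displacement, pollutant chemistry, and station siting pathologies beyond
bias + white noise. Passing tests therefore demonstrate correctness of
the estimators under the assumed data-generating process, not the
realism of any particular city's numbers.

## Validation

Stations are matched to the nearest cell centre by great-circle
(haversine) distance, ties broken to the lowest (row, column) index;
nearest-cell rather than bilinear sampling keeps the pairing conservative
at ~1 km granularity and the oracle trivial. Metrics per station: mean
bias (model − obs), MAE, RMSE, temporal Pearson R — which obey
RMSE ≥ MAE ≥ |bias| as an algebraic identity, asserted property-style.
Stations with fewer than 24 paired hours are excluded and logged. A
constant series makes Pearson R undefined; it is reported as a flagged
missing value, never silently 0. Network summaries are unweighted means
over stations plus a spatial correlation of station time-means against
matched-cell time-means.

## Reporting and numerics

Internal values are full precision; rounding happens only in the report
layer, half-to-even, integers for heat deaths and one decimal for
pollutant deaths. In the scenario totals table the total column is the
sum of the *rounded* stratum entries and the UHI row is differenced
before rounding, so the printed arithmetic is consistent by
construction. Derived percentages use the same half-to-even rule.
Degenerate inputs fail loudly everywhere (empty grids, zero masked
population, gapped series, negative concentrations, constant-series
correlations); no silent imputation is performed anywhere in the
pipeline.

## Problem sizes

Defaults were chosen so a full synthetic analysis (25 × 25 × 384 field,
30 stations, three strata) runs in well under a second, and the heavier
statistical checks (120 Poisson fits for slope recovery and CI coverage,
20 end-to-end Monte-Carlo replicates) in a few seconds, while keeping
every estimate comfortably inside its statistical tolerance.
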