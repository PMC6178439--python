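# ninocast

Forecasting the annual rise of atmospheric CO₂ at Mauna Loa from ENSO
sea-surface temperatures and anthropogenic emissions.

## The problem

Year-to-year fluctuations in the growth of atmospheric CO₂ are dominated by
the El Niño–Southern Oscillation: El Niño years weaken the tropical land
carbon sink, so more of the emitted carbon stays airborne. `ninocast`
implements the statistical forecast of the **annual increment** — the
difference between the annual-mean Mauna Loa concentrations of successive
calendar years — as a linear response to emissions and ENSO state:

```
ΔCO₂(i) = α₁ + α₂ · N(i) + α₃ · ε(i−1)
```

where `N(i)` is the mean Niño 3.4 SST anomaly over April (i−1) – March (i)
in °C (relative to a 1961–1990 baseline), `ε(i−1)` is the previous calendar
year's total anthropogenic emission in GtC, and the coefficients are fit by
ordinary least squares on the historical record. Around this core the
package provides:

- **time-series calendar arithmetic** — annual means, increments, in-year
  growth rates, seasonal adjustment factors and their amplitude trend, with
  an explicit gap policy for incomplete years (`ninocast.timeseries`);
- **ENSO predictor construction** — April–March window means over observed
  and seasonal-forecast SST ensemble members, spliced at a forecast date,
  with ensemble spread carried as a 2 s.d. half-width (`ninocast.enso`);
- **calibration & forecasting** — OLS fit (SVD, explicit rank check),
  verbatim coefficient injection for reproducing published tables, and
  downscaling of increments to annual and monthly means
  (`ninocast.regression`);
- **attribution** — counterfactual (N = 0) increments, the El Niño
  contribution and its fraction of the rise, no-El-Niño monthly estimates
  by counterfactual and by trend extrapolation (`ninocast.attribution`);
- **verification** — boundary-inclusive interval hits, monthly hit counts,
  and the long-run miss-rate calculus `1 − c^k` with `c` the Gaussian
  ±2 s.d. coverage (`ninocast.verification`);
- **synthetic data** — fully seeded generators for CO₂/SST/emissions input
  bundles with ground-truth bookkeeping, so the whole pipeline is testable
  without any downloads (`ninocast.synthetic`);
- **pipeline & CLI** — file-driven `run_forecast` / `run_hindcast` /
  `run_attribution` workflows with provenance records, wrapped by a thin
  `ninocast` command (`simulate`, `calibrate`, `forecast`, `hindcast`,
  `attribute`, `verify`).

## Worked example

The 2015→2016 forecast from published inputs (see
`examples/forecast_2016_worked.py`; all examples run in milliseconds):

```python
from ninocast import IncrementModel, predict_increment

model = IncrementModel(-0.132, 0.415, 0.237, fixed_two_sd=0.53)
inc, two_sd = predict_increment(model, nino=2.02, emissions=10.3)
print(f"{inc:.2f} ± {two_sd:.2f} ppm")   # -> 3.15 ± 0.53 ppm
```

With the forecast Niño 3.4 anomaly of 2.02 °C and projected 2015 emissions
of 10.3 GtC this predicts a record 3.15 ± 0.53 ppm rise; the observed rise
was 3.39 ppm — inside the range, a verified forecast. Attribution
(`examples/attribution_el_nino.py`) with the latest coefficients and
observed inputs prints:

```
2015/2016: with El Nino 3.21 ppm, without 2.42 ppm
  -> El Nino contributed 0.79 ppm (~25% of the rise)
```

i.e. roughly a quarter of the record rise came from the El Niño and the
rest from anthropogenic emissions; the counterfactual September 2016
estimate (400.34 ppm) says monthly CO₂ would have stayed above 400 ppm even
without it.

The other examples demonstrate forecast verification and the long-run miss
rate (`verification_calculus.py`) and a closed-loop run on synthetic data
with known ground truth (`synthetic_pipeline.py`).

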