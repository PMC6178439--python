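# Methods

## Model

The quantity forecast is the annual increment of the Mauna Loa CO₂
concentration, `ΔCO₂(i) = mean(year i) − mean(year i−1)` in ppm, modelled
as

    ΔCO₂(i) = α₁ + α₂ N(i) + α₃ ε(i−1) + η,   η ~ N(0, σ²)

with `N(i)` the April(i−1)–March(i) mean Niño 3.4 SST anomaly (°C, relative
to a 1961–1990 climatology) and `ε(i−1)` the previous calendar year's total
anthropogenic emission (fossil fuel + land use, GtC). The April–March
window is the one that correlates most strongly with the increment; it
shares exactly the three months January–March with the target calendar
year. The increment is deliberately distinct from the *in-year growth
rate* (change across one calendar year); both statistics are implemented,
the latter under a December-minus-December convention (see below).

Assumptions the model inherits and that the package makes explicit:

- the increment responds linearly to emissions and to the windowed ENSO
  anomaly, with residuals that are independent and roughly Gaussian; no
  autocorrelation modelling is attempted;
- the seasonal cycle is quasi-stationary, so a fixed set of twelve monthly
  adjustment factors (mean offset of each month from its year's annual
  mean; they sum to zero by construction) downscales an annual forecast to
  months; the `seasonal_amplitude_trend` diagnostic quantifies how well
  stationarity holds on a given record;
- the relationship breaks down after major volcanic eruptions (aerosol
  cooling); no exclusion is applied by default, but `calibrate` accepts an
  excluded-years list for sensitivity runs;
- the counterfactual ("no El Niño") baseline adds the N = 0 increment to
  the previous year's *observed* annual mean, ignoring any ENSO influence
  already embedded in that baseline. This is a known, accepted
  simplification; no correction is attempted.

## Calibration and uncertainty

OLS is solved by `numpy.linalg.lstsq` (SVD); rank deficiency is detected on
the column-scaled design with a relative singular-value cutoff of 1e-10 and
reported as an error rather than silently pseudo-inverted. `residual_sd`
is the sample (n−1) standard deviation of the residuals; coefficient
standard errors use the usual OLS covariance `σ̂²(XᵀX)⁻¹` with
`σ̂² = SSR/(n−3)`. At least four rows are required (three coefficients plus
one degree of freedom).

Forecast uncertainty policy: the default interval half-width is
`2 × residual_sd`; a `fixed_two_sd` override reproduces printed intervals
(e.g. ±0.53 ppm) exactly. Monthly forecast values carry the same
half-width as the annual mean — a simplification, since single-month errors
have extra variance that this policy does not model.

Published coefficient sets can be injected verbatim into `IncrementModel`
instead of calibrating, because the original calibration inputs (specific
historical dataset releases) are revised over time and are not
reconstructible from printed tables alone; all worked-number reproductions
use injection.

## ENSO predictor

Window means are equal-weight averages of the twelve monthly anomalies.
For a real-time forecast the window is spliced at the first
forecast-supplied month: observed ensemble members supply earlier months,
seasonal-forecast members the rest. Member pairing is index-based by
default (the j-th realization pairs observed member `j mod n_obs` with
forecast member `j mod n_fcst`, so the realization count is the larger
ensemble size); a full cross product is available via `pairing="cross"`.
The central value is the mean of the per-realization window means and the
spread twice their sample standard deviation (zero for a single
realization). Ties and spread conventions use the sample (n−1) estimator
throughout.

## Calendar conventions and degenerate inputs

- **Gap policy.** A year with any missing month has no annual mean by
  default (the error names the missing months); an opt-in policy
  interpolates a single missing month from its two calendar neighbours.
  Strictness is the default for reproducibility.
- **In-year growth.** "Start to end of the calendar year" is implemented
  as December(year) − December(year−1) monthly means; the convention is
  isolated in one function so alternatives (e.g. Nov–Feb averaging) can be
  swapped without touching anything else.
- **Interval hits are boundary-inclusive**; an observation exactly at the
  edge of the ±2 s.d. range counts as a hit.
- **Gaussian ±2 s.d. coverage** is computed from the error function
  (≈ 0.95450, per-year miss ≈ 4.55%), never hard-coded as 95%.
- Reported ppm/°C values are rounded to two decimals at the reporting
  layer only; all internal arithmetic is full precision.

## Synthetic data

The generator produces the three input families with the statistical
structure the model assumes, plus ground-truth bookkeeping (true window
means, realized increments, ENSO contributions, annual means):

- **ENSO index**: monthly AR(1), φ = 0.92, innovation s.d. 0.28 °C —
  persistence and spread chosen so April–March annual means span roughly
  −1.5 to +2.0 °C, the range of the historical record;
- **emissions**: exponential growth of 1.56 %/yr from 4.59 GtC at the 1958
  analogue, anchored analytically so the 2015 analogue emits ≈ 11.1 GtC,
  ≈ 2.7 GtC above the 1997 analogue; optional single-year spikes emulate
  land-use fire events;
- **CO₂**: annual increments generated *exactly* from the regression with
  residual s.d. 0.25 ppm (noise enters at the increment level, so the
  regression holds in expectation by construction; optional monthly
  observation noise is off by default), downscaled with a fixed
  Mauna-Loa-like seasonal shape of 6 ppm peak-to-trough, May maximum and
  September minimum. The shape is a fixed 12-month profile scaled to the
  configured amplitude and rotatable by its maximum month; the minimum
  follows the shape four months later rather than being independently
  settable;
- **SST ensembles**: members are truth plus independent Gaussian per-month
  noise of 0.35 °C, which makes the spliced April–March window spread
  ≈ 0.2 °C (2 s.d.), matching the uncertainty of the combined
  observed/forecast product.

All randomness flows from `numpy.random.default_rng([seed, stage])`, so
bundles are bit-reproducible across platforms and stages are independently
seeded.

What the generator does *not* emulate: volcanic interruptions of the
ENSO–CO₂ relationship, dataset revisions, drift or non-stationarity in the
seasonal cycle, spatially resolved SST fields, and observational gaps
(unless introduced by hand). Passing closed-loop tests therefore
demonstrates correctness of the machinery under the model's own
assumptions, not skill on real observations.

## Problem sizes

Default synthetic records span 1959–2016 (56–58 increment years, matching
the length of the historical calibration window). The Monte-Carlo
coefficient-recovery check uses 500 replicates of 56-year bundles; interval
calibration uses 1000 simulated forecast years. These sizes give binomial
standard errors comfortably inside the asserted tolerances
(e.g. ±1.5 percentage points on a 4.55% miss rate).

## Known limitations

- The regression is associative, not mechanistic: it summarises the
  land-sink response to ENSO but contains no process model, no volcanic
  forcing term, and no ocean-sink dynamics.
- Monthly downscaling inherits the annual error bar and the stationarity
  assumption; anomalous individual months (local meteorology at the
  observatory) will miss more often than the annual mean.
- The attribution fraction divides by the with-ENSO increment and is
  undefined when that increment is zero (flagged, not fabricated).
- Region choice for the SST index is the caller's: any anomaly series can
  be supplied, and events focused outside the Niño 3.4 box may be
  under-represented by it.
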