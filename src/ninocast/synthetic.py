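"""Synthetic input bundles with known ground truth.

Generates the three input families the forecast pipeline consumes — a
monthly CO2 record, monthly Nino-region SST anomaly ensembles (observed and
seasonal-forecast), and an annual emissions table — with the statistical
structure the increment regression assumes:

* the ENSO index is a monthly AR(1) process whose April–March annual means
  span roughly -1.5 to +2.0 degC at the default persistence;
* emissions grow smoothly (exponential trajectory anchored so the
  2015-analogue year emits ~11.1 GtC and sits ~2.7 GtC above the
  1997-analogue), with optional single-year spikes;
* annual CO2 increments are generated *exactly* from the regression
  equation plus a Gaussian residual, then downscaled to months with a
  fixed Mauna-Loa-like seasonal cycle (May maximum, September minimum),
  so calibration on noiseless bundles recovers the injected coefficients
  to numerical precision.

Every simulation draws from ``numpy.random.default_rng`` seeded from the
config seed plus a per-stage offset, so bundles are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, InputFormatError
from .timeseries import DEGC, PPM, EmissionsSeries, MonthlySeries, SeasonalCycle
from .enso import FORECAST, OBSERVED, EnsembleMonthlySeries, window_mean
from . import io as nio

# Mauna-Loa-like monthly offsets from the annual mean (ppm, Jan..Dec),
# de-meaned and rescaled to the configured peak-to-trough amplitude.
_BASE_SHAPE = np.array([0.3, 0.9, 1.7, 2.7, 3.2, 2.5, 0.7, -1.3, -3.0, -2.9, -1.7, -0.6])
_BASE_SHAPE = _BASE_SHAPE - _BASE_SHAPE.mean()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic bundle.

    ``start_year``/``end_year`` bound the increment years; the CO2 record
    spans the preceding calendar year through ``end_year`` and the ENSO
    series starts early enough to cover every April–March window.
    """

    start_year: int = 1959
    end_year: int = 2016
    alphas: tuple[float, float, float] = (-0.132, 0.415, 0.237)
    residual_sd: float = 0.25
    enso_phi: float = 0.92
    enso_innovation_sd: float = 0.28
    seasonal_peak_to_trough: float = 6.0
    seasonal_max_month: int = 5
    emissions_start_gtc: float = 4.59  # at start_year - 1
    emissions_growth: float = 0.0156  # fractional per year
    emissions_spikes: dict = field(default_factory=dict)  # year -> extra GtC
    n_obs_members: int = 10
    n_fcst_members: int = 20
    member_spread: float = 0.35  # degC per-month member noise s.d.
    forecast_split: tuple[int, int] | None = None  # default Nov(end_year - 1)
    base_co2: float = 315.0  # annual mean of start_year - 1
    monthly_obs_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.end_year - self.start_year + 1 < 10:
            raise InputFormatError("year range must span at least 10 years")
        if not 0.0 <= self.enso_phi < 1.0:
            raise InputFormatError("enso_phi must be in [0, 1)")
        for name in ("residual_sd", "enso_innovation_sd", "member_spread", "monthly_obs_noise_sd"):
            if getattr(self, name) < 0:
                raise InputFormatError(f"{name} must be non-negative")

    @property
    def split(self) -> tuple[int, int]:
        return self.forecast_split or (self.end_year - 1, 11)

    def seasonal_cycle(self) -> SeasonalCycle:
        shape = np.roll(_BASE_SHAPE, self.seasonal_max_month - 5)
        span = shape.max() - shape.min()
        return SeasonalCycle(shape * (self.seasonal_peak_to_trough / span))


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def simulate_nino(config: GeneratorConfig) -> MonthlySeries:
    """Monthly AR(1) SST anomaly covering every required April–March window."""
    rng = _rng(config, 1)
    start = pd.Period(year=config.start_year - 2, month=1, freq="M")
    end = pd.Period(year=config.end_year, month=12, freq="M")
    n = (end - start).n + 1
    phi, sd = config.enso_phi, config.enso_innovation_sd
    x = np.zeros(n)
    if sd > 0:
        stationary_sd = sd / np.sqrt(1.0 - phi**2)
        x[0] = rng.normal(0.0, stationary_sd)
        innov = rng.normal(0.0, sd, size=n - 1)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t - 1]
    idx = pd.period_range(start, end, freq="M")
    return MonthlySeries(pd.Series(x, index=idx), units=DEGC)


def simulate_emissions(config: GeneratorConfig) -> EmissionsSeries:
    """Exponentially growing annual emissions with optional year spikes."""
    years = np.arange(config.start_year - 1, config.end_year + 1)
    vals = config.emissions_start_gtc * (1.0 + config.emissions_growth) ** (
        years - (config.start_year - 1)
    )
    vals = vals.astype(float)
    for y, extra in config.emissions_spikes.items():
        vals[years == int(y)] += float(extra)
    return EmissionsSeries(pd.Series(vals, index=years))


@dataclass(frozen=True)
class CO2Truth:
    """Generator bookkeeping: what the synthetic CO2 record really contains."""

    alphas: tuple[float, float, float]
    nino_window: dict[int, float]  # year i -> true N(i)
    increments: dict[int, float]  # year i -> realized increment (incl. noise)
    contributions: dict[int, float]  # year i -> a2 * N(i)
    annual_means: dict[int, float]
    seasonal_factors: tuple[float, ...]


def simulate_co2(
    config: GeneratorConfig, nino: MonthlySeries, emissions: EmissionsSeries
) -> tuple[MonthlySeries, CO2Truth]:
    """Monthly CO2 record whose annual increments obey the regression exactly.

    Returns the series and the ground-truth bookkeeping (window means,
    realized increments, ENSO contributions, annual means).
    """
    a1, a2, a3 = config.alphas
    rng = _rng(config, 2)
    years = range(config.start_year, config.end_year + 1)
    annual = {config.start_year - 1: float(config.base_co2)}
    n_win: dict[int, float] = {}
    incs: dict[int, float] = {}
    contribs: dict[int, float] = {}
    for i in years:
        try:
            n_i = window_mean(nino, i)
        except CoverageError as exc:
            raise CoverageError(f"nino series does not cover year {i}: {exc}") from exc
        eps = emissions.value(i - 1)
        noise = rng.normal(0.0, config.residual_sd) if config.residual_sd > 0 else 0.0
        inc = a1 + a2 * n_i + a3 * eps + noise
        annual[i] = annual[i - 1] + inc
        n_win[i], incs[i], contribs[i] = n_i, inc, a2 * n_i
    cycle = config.seasonal_cycle()
    obs_noise = config.monthly_obs_noise_sd
    records = []
    for y in sorted(annual):
        for m in range(1, 13):
            v = annual[y] + cycle.factor(m)
            if obs_noise > 0:
                v += rng.normal(0.0, obs_noise)
            records.append((y, m, v))
    series = MonthlySeries.from_records(records, units=PPM)
    truth = CO2Truth(
        alphas=tuple(config.alphas),
        nino_window=n_win,
        increments=incs,
        contributions=contribs,
        annual_means=annual,
        seasonal_factors=tuple(cycle.factors),
    )
    return series, truth


def simulate_sst_ensembles(
    config: GeneratorConfig, nino: MonthlySeries
) -> tuple[EnsembleMonthlySeries, EnsembleMonthlySeries]:
    """Observed and forecast member ensembles around the true ENSO series.

    Observed members span the full series; forecast members cover only the
    forecast horizon, from the split month through March of the final year.
    Members are truth plus independent Gaussian per-month noise.
    """
    rng = _rng(config, 3)
    idx = nino.data.index
    truth_vals = nino.data.to_numpy()

    def _member(mask) -> MonthlySeries:
        sub_idx = idx[mask]
        noise = (
            rng.normal(0.0, config.member_spread, size=len(sub_idx))
            if config.member_spread > 0
            else np.zeros(len(sub_idx))
        )
        return MonthlySeries(pd.Series(truth_vals[mask] + noise, index=sub_idx), units=DEGC)

    full = np.ones(len(idx), dtype=bool)
    obs = EnsembleMonthlySeries(
        members={f"obs{k:02d}": _member(full) for k in range(config.n_obs_members)},
        source=OBSERVED,
    )
    split_p = pd.Period(year=config.split[0], month=config.split[1], freq="M")
    end_p = pd.Period(year=config.end_year, month=3, freq="M")
    horizon = (idx >= split_p) & (idx <= end_p)
    fcst = EnsembleMonthlySeries(
        members={f"fc{k:02d}": _member(horizon) for k in range(config.n_fcst_members)},
        source=FORECAST,
    )
    return obs, fcst


@dataclass(frozen=True)
class Bundle:
    """An in-memory synthetic input bundle plus its ground truth."""

    config: GeneratorConfig
    co2: MonthlySeries
    nino: MonthlySeries
    emissions: EmissionsSeries
    obs_ensemble: EnsembleMonthlySeries
    fcst_ensemble: EnsembleMonthlySeries
    truth: CO2Truth


def generate_bundle(config: GeneratorConfig) -> Bundle:
    """Generate all inputs and bookkeeping for one seed."""
    nino = simulate_nino(config)
    emissions = simulate_emissions(config)
    co2, truth = simulate_co2(config, nino, emissions)
    obs, fcst = simulate_sst_ensembles(config, nino)
    return Bundle(config, co2, nino, emissions, obs, fcst, truth)


def write_fixture_bundle(config: GeneratorConfig, directory) -> dict[str, Path]:
    """Write a bundle as CSV inputs plus a JSON ground-truth sidecar.

    Files: ``co2.csv``, ``emissions.csv``, ``sst_ensembles.csv`` (long
    format, observed + forecast), ``truth.json``.  Returns the paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    paths = {
        "co2": directory / "co2.csv",
        "emissions": directory / "emissions.csv",
        "sst": directory / "sst_ensembles.csv",
        "truth": directory / "truth.json",
    }
    try:
        nio.write_co2_csv(bundle.co2, paths["co2"])
        nio.write_emissions_csv(bundle.emissions, paths["emissions"])
        nio.write_ensemble_csv(
            {OBSERVED: bundle.obs_ensemble, FORECAST: bundle.fcst_ensemble}, paths["sst"]
        )
        truth = bundle.truth
        sidecar = {
            "alphas": list(truth.alphas),
            "nino_window": {str(k): v for k, v in truth.nino_window.items()},
            "increments": {str(k): v for k, v in truth.increments.items()},
            "contributions": {str(k): v for k, v in truth.contributions.items()},
            "annual_means": {str(k): v for k, v in truth.annual_means.items()},
            "seasonal_factors": list(truth.seasonal_factors),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
        }
        paths["truth"].write_text(json.dumps(sidecar, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing bundle under {directory}: {exc}") from exc
    return paths


def read_truth_sidecar(path) -> CO2Truth:
    d = json.loads(Path(path).read_text())
    return CO2Truth(
        alphas=tuple(d["alphas"]),
        nino_window={int(k): v for k, v in d["nino_window"].items()},
        increments={int(k): v for k, v in d["increments"].items()},
        contributions={int(k): v for k, v in d["contributions"].items()},
        annual_means={int(k): v for k, v in d["annual_means"].items()},
        seasonal_factors=tuple(d["seasonal_factors"]),
    )
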