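"""End-to-end workflows: forecast, hindcast, attribution, verification.

Each run function loads the three input files (monthly CO2 CSV, long-format
SST anomaly ensemble CSV, annual emissions CSV), executes the stages of the
forecast method, writes tidy CSV + plain-text reports into the output
directory when one is configured, and records a provenance snapshot
(config, input digests, package version) sufficient to re-run the
computation bit-identically.

The forecast workflow mirrors the real-time procedure: the ENSO predictor
splices observed SST months before the forecast split date with seasonal
forecast members after it.  The hindcast swaps in fully observed SSTs and
observed emissions; the attribution re-evaluates the calibrated model with
the SST anomaly zeroed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import CoverageError, InputFormatError
from .timeseries import (
    EmissionsSeries,
    MonthlySeries,
    SeasonalCycle,
    annual_mean,
    seasonal_factors,
)
from .enso import EnsembleMonthlySeries, WindowedNino, combine_obs_forecast, observed_window
from .attribution import AttributionResult, counterfactual_increment, enso_contribution
from .regression import (
    ForecastResult,
    IncrementModel,
    build_design_rows,
    calibrate,
    forecast_concentrations,
    increment_components,
    predict_increment,
)
from . import io as nio

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one seasonal-factor source must be set: either
    ``seasonal_reference_years`` (factors computed from the CO2 record) or
    ``seasonal_factor_values`` (twelve injected factors, e.g. a published
    adjustment table).  A ``coefficients`` override bypasses calibration and
    is recorded in provenance.
    """

    co2_path: str
    emissions_path: str
    sst_path: str
    target_year: int
    calibration_years: tuple[int, int] = (1959, 2014)
    coefficients: tuple[float, float, float] | None = None
    fixed_two_sd: float | None = None
    seasonal_reference_years: tuple[int, int] | None = None
    seasonal_factor_values: tuple[float, ...] | None = None
    split: tuple[int, int] | None = None  # first forecast-supplied month
    excluded_years: tuple[int, ...] = ()
    pairing: str = "index"
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        has_range = self.seasonal_reference_years is not None
        has_values = self.seasonal_factor_values is not None
        if has_range == has_values:
            raise InputFormatError(
                "exactly one seasonal-factor source required: "
                "seasonal_reference_years or seasonal_factor_values"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise InputFormatError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("calibration_years", "seasonal_reference_years", "split",
                    "coefficients", "seasonal_factor_values", "excluded_years"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class LoadedInputs:
    co2: MonthlySeries
    emissions: EmissionsSeries
    obs: EnsembleMonthlySeries
    fcst: EnsembleMonthlySeries | None


def load_inputs(config: RunConfig) -> LoadedInputs:
    co2 = nio.read_co2_csv(config.co2_path)
    emissions = nio.read_emissions_csv(config.emissions_path)
    ensembles = nio.read_ensemble_csv(config.sst_path)
    if "observed" not in ensembles:
        raise InputFormatError(f"{config.sst_path}: no observed SST members")
    return LoadedInputs(co2, emissions, ensembles["observed"], ensembles.get("forecast"))


def _seasonal_cycle(config: RunConfig, co2: MonthlySeries) -> SeasonalCycle:
    if config.seasonal_factor_values is not None:
        return SeasonalCycle.from_factors(config.seasonal_factor_values)
    return seasonal_factors(co2, config.seasonal_reference_years)


def _calibrated_model(config: RunConfig, inputs: LoadedInputs) -> IncrementModel:
    if config.coefficients is not None:
        a1, a2, a3 = config.coefficients
        return IncrementModel(a1, a2, a3, fixed_two_sd=config.fixed_two_sd)
    lo, hi = config.calibration_years
    nino_by_year: dict[int, WindowedNino] = {}
    for i in range(lo, hi + 1):
        try:
            nino_by_year[i] = observed_window(inputs.obs, i)
        except CoverageError as exc:
            log.info("no observed ENSO window for %d: %s", i, exc)
    rows = build_design_rows(inputs.co2, nino_by_year, inputs.emissions, range(lo, hi + 1))
    return calibrate(rows, excluded_years=config.excluded_years, fixed_two_sd=config.fixed_two_sd)


def _input_digests(config: RunConfig) -> dict[str, str]:
    out = {}
    for key in ("co2_path", "emissions_path", "sst_path"):
        p = Path(getattr(config, key))
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return out


def _write_provenance(config: RunConfig, stage: str, outdir: Path) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "input_sha256": _input_digests(config),
    }
    (outdir / f"{stage}_provenance.json").write_text(json.dumps(record, indent=1))


def _emit_forecast_reports(config: RunConfig, stage: str, result: ForecastResult,
                           model: IncrementModel, nino: WindowedNino) -> None:
    if config.output_dir is None:
        return
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.monthly_frame().to_csv(outdir / f"{stage}_monthly.csv", index=False, float_format="%.4f")
    lines = [
        f"{stage} for {result.target_year}",
        f"  alphas            : ({model.alpha1:.3f}, {model.alpha2:.3f}, {model.alpha3:.3f})",
        f"  N (degC)          : {nino.central:.2f} +/- {nino.two_sd:.2f}",
        f"  increment (ppm)   : {result.increment_central:.2f} +/- {result.increment_two_sd:.2f}",
        f"  annual mean (ppm) : {result.annual_mean:.2f}",
    ]
    (outdir / f"{stage}_summary.txt").write_text("\n".join(lines) + "\n")
    _write_provenance(config, stage, outdir)


def _forecast_from_nino(config: RunConfig, inputs: LoadedInputs, nino: WindowedNino,
                        stage: str) -> ForecastResult:
    model = _calibrated_model(config, inputs)
    eps = inputs.emissions.value(config.target_year - 1)
    increment, two_sd = predict_increment(model, nino.central, eps)
    cycle = _seasonal_cycle(config, inputs.co2)
    prev = annual_mean(inputs.co2, config.target_year - 1)
    result = forecast_concentrations(
        prev,
        increment,
        cycle,
        increment_two_sd=two_sd,
        target_year=config.target_year,
        components=increment_components(model, nino.central, eps),
    )
    log.info(
        "%s %d: N=%.3f degC, eps=%.3f GtC, increment=%.3f ppm, annual=%.3f ppm",
        stage, config.target_year, nino.central, eps, increment, result.annual_mean,
    )
    _emit_forecast_reports(config, stage, result, model, nino)
    return result


def run_forecast(config: RunConfig) -> ForecastResult:
    """Real-time-style forecast: spliced observed + forecast ENSO window."""
    inputs = load_inputs(config)
    if inputs.fcst is None:
        raise InputFormatError("forecast run requires forecast SST members")
    split = config.split or (config.target_year - 1, 11)
    nino = combine_obs_forecast(
        inputs.obs, inputs.fcst, split, config.target_year, pairing=config.pairing
    )
    return _forecast_from_nino(config, inputs, nino, "forecast")


def run_hindcast(config: RunConfig) -> ForecastResult:
    """Retrospective forecast with fully observed SST and emissions."""
    inputs = load_inputs(config)
    nino = observed_window(inputs.obs, config.target_year)
    return _forecast_from_nino(config, inputs, nino, "hindcast")


def run_attribution(config: RunConfig) -> AttributionResult:
    """With/without-ENSO decomposition of the target-year increment."""
    inputs = load_inputs(config)
    model = _calibrated_model(config, inputs)
    nino = observed_window(inputs.obs, config.target_year)
    eps = inputs.emissions.value(config.target_year - 1)
    with_nino, _ = predict_increment(model, nino.central, eps)
    without = counterfactual_increment(model, eps)
    result = enso_contribution(with_nino, without, target_year=config.target_year)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "attribution_summary.txt").write_text(result.to_text() + "\n")
        frame_rows = [
            ("with_el_nino_ppm", result.with_nino),
            ("no_el_nino_ppm", result.without_nino),
            ("contribution_ppm", result.contribution),
            ("fraction_percent", result.fraction_percent),
        ]
        import pandas as pd

        pd.DataFrame(frame_rows, columns=["quantity", "value"]).to_csv(
            outdir / "attribution.csv", index=False
        )
        _write_provenance(config, "attribution", outdir)
    return result
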