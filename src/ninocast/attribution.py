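"""Counterfactual (no-El-Nino) increments and ENSO attribution.

The contribution of an El Nino to a year's CO2 rise is estimated by
re-evaluating the increment regression with the SST anomaly zeroed
(``N = 0``) and differencing against the with-ENSO prediction made with the
same model.  Under the model this difference is exactly the ENSO term
``a2 * N``.  The counterfactual annual mean adds the counterfactual
increment to the previous year's observed annual mean — a baseline that
deliberately ignores any ENSO influence already embedded in that previous
year (the simple-methodology assumption; no correction is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputFormatError
from .regression import IncrementModel, predict_increment
from .timeseries import SeasonalCycle


@dataclass(frozen=True)
class AttributionResult:
    """With/without-ENSO increment decomposition for one target year."""

    target_year: int
    with_nino: float
    without_nino: float
    contribution: float
    fraction: float | None  # raw ratio, None when with_nino == 0
    fraction_percent: int | None  # nearest-integer percent for reporting

    def to_text(self) -> str:
        frac = "undefined" if self.fraction_percent is None else f"~{self.fraction_percent}%"
        return "\n".join(
            [
                f"ENSO attribution, target year {self.target_year}",
                f"  increment with El Nino    : {self.with_nino:.2f} ppm",
                f"  increment without El Nino : {self.without_nino:.2f} ppm",
                f"  El Nino contribution      : {self.contribution:.2f} ppm ({frac} of the rise)",
            ]
        )


def counterfactual_increment(model: IncrementModel, emissions: float) -> float:
    """Central increment with the SST anomaly zeroed (N = 0)."""
    central, _ = predict_increment(model, 0.0, emissions)
    return central


def enso_contribution(with_nino: float, without_nino: float, target_year: int = 0) -> AttributionResult:
    """Difference and fractional share of the with-ENSO increment.

    The fraction is reported rounded to the nearest integer percent; it is
    undefined (flagged None) when the with-ENSO increment is zero.
    """
    contribution = with_nino - without_nino
    if with_nino != 0.0:
        fraction = contribution / with_nino
        percent = round(100.0 * fraction)
    else:
        fraction = None
        percent = None
    return AttributionResult(
        target_year=target_year,
        with_nino=float(with_nino),
        without_nino=float(without_nino),
        contribution=float(contribution),
        fraction=fraction,
        fraction_percent=percent,
    )


def no_nino_monthly(
    prev_annual_mean: float,
    counterfactual_inc: float,
    cycle: SeasonalCycle,
    month: int,
) -> float:
    """Counterfactual monthly concentration: annual no-ENSO mean + month factor."""
    if not 1 <= month <= 12:
        raise InputFormatError(f"month must be in 1..12, got {month}")
    return (prev_annual_mean + counterfactual_inc) + cycle.factor(month)


def trend_extrapolation(monthly_value: float, trend: float, n_years: int) -> float:
    """Project a monthly concentration forward along a fixed linear trend."""
    if n_years < 0:
        raise InputFormatError("n_years must be non-negative")
    return monthly_value + trend * n_years
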