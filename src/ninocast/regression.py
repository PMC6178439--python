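"""The annual CO2 increment regression and its forecasts.

The model is a three-coefficient multiple linear regression

    dCO2(i) = a1 + a2 * N(i) + a3 * eps(i - 1)

where ``dCO2(i)`` is the annual increment of the Mauna Loa concentration
between calendar years ``i - 1`` and ``i`` (ppm), ``N(i)`` is the mean
Nino 3.4 SST anomaly over April(i-1)–March(i) (degC), and ``eps(i-1)`` is
the total anthropogenic emission of the previous calendar year (GtC —
emissions tables are published per calendar year, hence the one-year lag).

Calibration is ordinary least squares solved by an orthogonal (SVD)
decomposition with an explicit rank check; coefficients may instead be
injected verbatim (published tables) to reproduce printed forecasts.
A forecast increment is downscaled to an annual mean by adding it to the
previous year's observed annual mean, and to monthly means by adding the
seasonal adjustment factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import InputFormatError, MissingMonthsError, RankDeficientError
from .timeseries import EmissionsSeries, MonthlySeries, SeasonalCycle, annual_increment
from .enso import WindowedNino

log = logging.getLogger(__name__)

RANK_TOL = 1e-10  # relative singular-value cutoff on column-scaled design


class DesignRow(NamedTuple):
    """One calibration row: (year i, dCO2(i) ppm, N(i) degC, eps(i-1) GtC)."""

    year: int
    delta_co2: float
    nino: float
    emissions_prev: float


@dataclass(frozen=True)
class IncrementModel:
    """Calibrated (or injected) coefficients of the increment regression.

    ``alpha1`` is the intercept (ppm/yr), ``alpha2`` the ENSO sensitivity
    (ppm/yr per degC), ``alpha3`` the airborne response to emissions
    (ppm per GtC).  ``residual_sd`` is the sample standard deviation of the
    calibration residuals; the default forecast uncertainty is twice that,
    unless ``fixed_two_sd`` pins the printed interval half-width.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    residual_sd: float = 0.0
    calibration_years: tuple[int, int] | None = None
    n_rows: int | None = None
    alpha_se: tuple[float, float, float] | None = None
    fixed_two_sd: float | None = None

    def __post_init__(self):
        if self.residual_sd < 0:
            raise InputFormatError("residual_sd must be non-negative")
        if self.n_rows is not None and self.n_rows < 4:
            raise InputFormatError("a calibrated model needs at least 4 rows")

    @property
    def alphas(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    @property
    def two_sd(self) -> float:
        return self.fixed_two_sd if self.fixed_two_sd is not None else 2.0 * self.residual_sd


@dataclass(frozen=True)
class ForecastResult:
    """A forecast increment with its downscaled annual and monthly means."""

    target_year: int
    increment_central: float
    increment_two_sd: float
    annual_mean: float
    monthly_means: np.ndarray  # 12 values, Jan..Dec
    components: tuple[float, float, float] | None = None  # (a1, a2*N, a3*eps)

    def __post_init__(self):
        mm = np.asarray(self.monthly_means, dtype=float)
        if mm.shape != (12,):
            raise InputFormatError("monthly_means needs 12 values")
        object.__setattr__(self, "monthly_means", mm)
        if self.components is not None and abs(sum(self.components) - self.increment_central) > 1e-9:
            raise InputFormatError("components must sum to the central increment")

    def monthly_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": np.arange(1, 13),
                "forecast_ppm": self.monthly_means,
                "two_sd_ppm": self.increment_two_sd,
            }
        )


def build_design_rows(
    co2: MonthlySeries,
    nino: Mapping[int, float | WindowedNino],
    emissions: EmissionsSeries,
    years: Iterable[int],
) -> list[DesignRow]:
    """Assemble one regression row per resolvable year; log and drop the rest."""
    rows: list[DesignRow] = []
    for i in years:
        try:
            d = annual_increment(co2, i)
            n = nino[i]
            if isinstance(n, WindowedNino):
                n = n.central
            e = emissions.value(i - 1)
        except (KeyError, MissingMonthsError) as exc:
            log.info("dropping calibration year %d: %s", i, exc)
            continue
        rows.append(DesignRow(int(i), float(d), float(n), float(e)))
    if not rows:
        raise InputFormatError("no calibration rows could be assembled")
    return rows


def _design_matrix(rows: list[DesignRow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[1.0, r.nino, r.emissions_prev] for r in rows])
    y = np.array([r.delta_co2 for r in rows])
    return X, y


def calibrate(
    rows: list[DesignRow],
    excluded_years: Iterable[int] = (),
    fixed_two_sd: float | None = None,
) -> IncrementModel:
    """Ordinary least squares fit of the increment regression.

    ``excluded_years`` drops e.g. post-eruption years for sensitivity runs.
    Raises :class:`RankDeficientError` when the column-scaled design has a
    relative singular value below ``1e-10`` (collinear predictors).
    """
    excluded = set(int(y) for y in excluded_years)
    rows = [r for r in rows if r.year not in excluded]
    if len(rows) < 4:
        raise InputFormatError(f"need at least 4 rows to calibrate, got {len(rows)}")
    X, y = _design_matrix(rows)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise RankDeficientError("a design column is identically zero")
    sv = np.linalg.svd(X / norms, compute_uv=False)
    if sv[-1] < RANK_TOL * sv[0]:
        raise RankDeficientError(
            f"design matrix is rank deficient (relative sv {sv[-1] / sv[0]:.2e}); "
            "predictors are collinear"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    residual_sd = float(np.std(resid, ddof=1))
    dof = len(rows) - 3
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        alpha_se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    else:
        alpha_se = None
    yrs = (min(r.year for r in rows), max(r.year for r in rows))
    return IncrementModel(
        alpha1=float(beta[0]),
        alpha2=float(beta[1]),
        alpha3=float(beta[2]),
        residual_sd=residual_sd,
        calibration_years=yrs,
        n_rows=len(rows),
        alpha_se=alpha_se,
        fixed_two_sd=fixed_two_sd,
    )


def predict_increment(model: IncrementModel, nino: float, emissions: float) -> tuple[float, float]:
    """Central increment a1 + a2*N + a3*eps and its 2 s.d. half-width (ppm)."""
    if not (np.isfinite(nino) and np.isfinite(emissions)):
        raise InputFormatError("nino and emissions must be finite")
    central = model.alpha1 + model.alpha2 * nino + model.alpha3 * emissions
    return float(central), float(model.two_sd)


def increment_components(model: IncrementModel, nino: float, emissions: float) -> tuple[float, float, float]:
    """The three additive terms (intercept, ENSO term, emissions term)."""
    return (model.alpha1, model.alpha2 * nino, model.alpha3 * emissions)


def reconstruct_history(model: IncrementModel, rows: list[DesignRow]) -> pd.Series:
    """Fitted increments for every design row, indexed by year."""
    fitted = {
        r.year: predict_increment(model, r.nino, r.emissions_prev)[0] for r in rows
    }
    return pd.Series(fitted, name="reconstructed_increment_ppm").sort_index()


def forecast_concentrations(
    prev_annual_mean: float,
    increment: float,
    cycle: SeasonalCycle,
    *,
    increment_two_sd: float = 0.0,
    target_year: int = 0,
    components: tuple[float, float, float] | None = None,
) -> ForecastResult:
    """Downscale a forecast increment to annual and monthly concentrations.

    The annual mean is the previous year's observed annual mean plus the
    increment; monthly means add the seasonal adjustment factors (which sum
    to zero, so the monthly means average back to the annual mean).
    """
    annual = prev_annual_mean + increment
    monthly = annual + cycle.factors
    return ForecastResult(
        target_year=target_year,
        increment_central=float(increment),
        increment_two_sd=float(increment_two_sd),
        annual_mean=float(annual),
        monthly_means=monthly,
        components=components,
    )


# ---------------------------------------------------------------------------
# plain-text model serialization

_MODEL_FIELDS = ("alpha1", "alpha2", "alpha3", "residual_sd", "fixed_two_sd")


def save_model(model: IncrementModel, path) -> None:
    """Write the model as plain ``key = value`` text."""
    lines = [f"{k} = {getattr(model, k)!r}" for k in _MODEL_FIELDS]
    if model.calibration_years:
        lines.append(f"calibration_years = {model.calibration_years[0]}..{model.calibration_years[1]}")
    if model.n_rows is not None:
        lines.append(f"n_rows = {model.n_rows}")
    if model.alpha_se is not None:
        lines.append("alpha_se = " + ", ".join(f"{s!r}" for s in model.alpha_se))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> IncrementModel:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()

    def _float(key, default=None):
        v = kv.get(key)
        if v is None or v == "None":
            return default
        return float(v)

    years = None
    if "calibration_years" in kv:
        lo, hi = kv["calibration_years"].split("..")
        years = (int(lo), int(hi))
    se = None
    if "alpha_se" in kv:
        se = tuple(float(x) for x in kv["alpha_se"].split(","))
    return IncrementModel(
        alpha1=_float("alpha1"),
        alpha2=_float("alpha2"),
        alpha3=_float("alpha3"),
        residual_sd=_float("residual_sd", 0.0),
        fixed_two_sd=_float("fixed_two_sd"),
        calibration_years=years,
        n_rows=int(kv["n_rows"]) if "n_rows" in kv else None,
        alpha_se=se,
    )
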