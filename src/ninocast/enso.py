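"""Windowed Nino-region SST anomalies from observed and forecast ensembles.

The ENSO predictor of the increment regression is ``N``, the mean Nino 3.4
SST anomaly over the twelve months from April of year ``i - 1`` through
March of year ``i`` — the window found to correlate most strongly with the
annual CO2 increment attributed to year ``i``.

Both the observational SST product and the seasonal forecast are ensembles:
observed members sample measurement/sampling uncertainty, forecast members
sample initial-condition sensitivity.  A real-time forecast window splices
observed months (before the forecast split date) with forecast months, one
spliced realization per member pair; the spread of the per-realization
window means carries the uncertainty forward as a 2 s.d. half-width.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .errors import CoverageError, InputFormatError
from .timeseries import DEGC, MonthlySeries

OBSERVED = "observed"
FORECAST = "forecast"


@dataclass(frozen=True)
class EnsembleMonthlySeries:
    """A set of monthly anomaly series indexed by member id."""

    members: dict[str, MonthlySeries]
    source: str = OBSERVED  # "observed" | "forecast"

    def __post_init__(self):
        if self.source not in (OBSERVED, FORECAST):
            raise InputFormatError(f"source must be observed/forecast, got {self.source!r}")
        units = {m.units for m in self.members.values()}
        if len(units) > 1:
            raise InputFormatError(f"members mix units: {units}")

    def member_ids(self) -> list[str]:
        return sorted(self.members)

    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class WindowedNino:
    """April–March window mean of the Nino anomaly for a target year."""

    target_year: int
    central: float
    two_sd: float
    realizations: tuple[float, ...] = ()

    def __post_init__(self):
        if self.two_sd < 0:
            raise InputFormatError("two_sd must be non-negative")


def window_periods(target_year: int) -> list[pd.Period]:
    """The 12 monthly periods Apr(i-1)..Mar(i) for target year ``i``."""
    start = pd.Period(year=target_year - 1, month=4, freq="M")
    return [start + k for k in range(12)]


def window_mean(member: MonthlySeries, target_year: int) -> float:
    """Equal-weight mean anomaly over Apr(i-1)..Mar(i)."""
    vals, missing = [], []
    for p in window_periods(target_year):
        if member.has(p.year, p.month):
            vals.append(member.value(p.year, p.month))
        else:
            missing.append(f"{p.year}-{p.month:02d}")
    if missing:
        raise CoverageError(
            f"window for {target_year} missing months: {', '.join(missing)}"
        )
    return float(np.mean(vals))


def ensemble_summary(realizations) -> tuple[float, float]:
    """Mean and twice the sample (n-1) standard deviation of realizations.

    A single realization has zero spread by convention.
    """
    vals = np.asarray(list(realizations), dtype=float)
    if vals.size == 0:
        raise InputFormatError("empty realization list")
    central = float(vals.mean())
    two_sd = 0.0 if vals.size == 1 else float(2.0 * vals.std(ddof=1))
    return central, two_sd


def combine_obs_forecast(
    obs: EnsembleMonthlySeries,
    fcst: EnsembleMonthlySeries,
    split: tuple[int, int],
    target_year: int,
    pairing: str = "index",
) -> WindowedNino:
    """Windowed N from observed months up to the split, forecast months after.

    ``split`` is the (year, month) of the first forecast-supplied month.
    Pairing of members:

    * ``"index"`` (default) — the j-th realization splices observed member
      ``j mod n_obs`` with forecast member ``j mod n_fcst``, giving
      ``max(n_obs, n_fcst)`` realizations (smaller ensemble recycled);
    * ``"cross"`` — full cross product of observed and forecast members.

    A split at or before the window start degenerates to a pure-forecast
    window; at or after the window end, to a pure-observation window.
    """
    if pairing not in ("index", "cross"):
        raise InputFormatError(f"pairing must be index/cross, got {pairing!r}")
    split_p = pd.Period(year=split[0], month=split[1], freq="M")
    window = window_periods(target_year)
    obs_months = [p for p in window if p < split_p]
    fcst_months = [p for p in window if p >= split_p]

    obs_ids = obs.member_ids()
    fcst_ids = fcst.member_ids()
    if obs_months and not obs_ids:
        raise CoverageError("observed ensemble empty but observed months required")
    if fcst_months and not fcst_ids:
        raise CoverageError("forecast ensemble empty but forecast months required")
    # degenerate sides need a placeholder id so the pairing loops run
    obs_ids = obs_ids or [None]
    fcst_ids = fcst_ids or [None]

    if pairing == "cross":
        pairs = list(product(obs_ids, fcst_ids))
    else:
        n = max(len(obs_ids), len(fcst_ids))
        pairs = [(obs_ids[j % len(obs_ids)], fcst_ids[j % len(fcst_ids)]) for j in range(n)]

    realizations = []
    for oid, fid in pairs:
        om = obs.members[oid] if oid is not None else None
        fm = fcst.members[fid] if fid is not None else None
        vals = []
        if obs_months:
            vals.append(sum(_member_values(om, obs_months)))
        if fcst_months:
            vals.append(sum(_member_values(fm, fcst_months)))
        realizations.append(sum(vals) / 12.0)

    central, two_sd = ensemble_summary(realizations)
    return WindowedNino(target_year, central, two_sd, tuple(realizations))


def _member_values(member: MonthlySeries, months: list[pd.Period]) -> list[float]:
    vals, missing = [], []
    for p in months:
        if member.has(p.year, p.month):
            vals.append(member.value(p.year, p.month))
        else:
            missing.append(f"{p.year}-{p.month:02d}")
    if missing:
        raise CoverageError(f"{member.units} member missing months: {', '.join(missing)}")
    return vals


def observed_window(obs: EnsembleMonthlySeries, target_year: int) -> WindowedNino:
    """Windowed N from a fully observed ensemble (hindcast input)."""
    if not obs.members:
        raise CoverageError("empty ensemble")
    realizations = [window_mean(m, target_year) for _, m in sorted(obs.members.items())]
    central, two_sd = ensemble_summary(realizations)
    return WindowedNino(target_year, central, two_sd, tuple(realizations))


def anomalies_from_absolute(series: MonthlySeries, climatology) -> MonthlySeries:
    """Convert an absolute series to anomalies given a 12-value monthly climatology."""
    clim = np.asarray(climatology, dtype=float)
    if clim.shape != (12,):
        raise InputFormatError("climatology needs 12 monthly values")
    idx = series.data.index
    anoms = series.data.to_numpy() - clim[idx.month - 1]
    return MonthlySeries(pd.Series(anoms, index=idx), units=DEGC)
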