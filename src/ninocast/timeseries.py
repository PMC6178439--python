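"""Monthly time-series containers and calendar statistics.

The central object is :class:`MonthlySeries`, a gap-aware monthly record of
a single scalar quantity (CO2 mole fraction in ppm, or an SST anomaly in
degrees Celsius).  Missing months are simply absent; every derived annual
statistic either demands complete coverage or applies an explicit,
documented gap policy.

Annual statistics distinguish two notions of "how fast CO2 rose":

* the *annual increment* — the difference between the annual mean
  concentrations of two successive calendar years, indexed by the later
  year; and
* the *in-year growth rate* — the change across a single calendar year,
  here taken as December(year) minus December(year-1) monthly means.

The seasonal cycle is summarised by twelve monthly adjustment factors, the
mean offset of each calendar month from its year's annual mean.  Adding the
factors back onto an annual-mean forecast downscales it to months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputFormatError, MissingMonthsError

PPM = "ppm"
DEGC = "degC"

_VALID_UNITS = (PPM, DEGC)


def _period(year: int, month: int) -> pd.Period:
    if not 1 <= int(month) <= 12:
        raise InputFormatError(f"month must be in 1..12, got {month!r}")
    return pd.Period(year=int(year), month=int(month), freq="M")


@dataclass(frozen=True)
class MonthlySeries:
    """An ordered monthly record of one scalar quantity.

    Parameters
    ----------
    data : pandas.Series
        Values indexed by a monthly ``PeriodIndex``; gaps are absent index
        entries, never NaN.
    units : str
        Either ``"ppm"`` or ``"degC"``.
    """

    data: pd.Series
    units: str = PPM

    def __post_init__(self):
        if self.units not in _VALID_UNITS:
            raise InputFormatError(f"units must be one of {_VALID_UNITS}, got {self.units!r}")
        s = self.data
        if not isinstance(s.index, pd.PeriodIndex) or s.index.freqstr not in ("M", "ME"):
            raise InputFormatError("MonthlySeries requires a monthly PeriodIndex")
        if s.index.has_duplicates:
            dupes = s.index[s.index.duplicated()].tolist()
            raise InputFormatError(f"duplicate (year, month) entries: {dupes}")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
        vals = np.asarray(s, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InputFormatError("non-finite values are not allowed; drop sentinels at read time")
        object.__setattr__(self, "data", pd.Series(vals, index=s.index, name=self.units))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[int, int, float]], units: str = PPM) -> "MonthlySeries":
        """Build from an iterable of ``(year, month, value)`` tuples."""
        records = list(records)
        if not records:
            raise InputFormatError("empty record set")
        idx = pd.PeriodIndex([_period(y, m) for y, m, _ in records])
        vals = [float(v) for _, _, v in records]
        return cls(pd.Series(vals, index=idx), units=units)

    # -- access -----------------------------------------------------------

    def value(self, year: int, month: int) -> float:
        p = _period(year, month)
        try:
            return float(self.data.loc[p])
        except KeyError:
            raise MissingMonthsError(f"no value for {year}-{month:02d}", [(year, month)]) from None

    def has(self, year: int, month: int) -> bool:
        return _period(year, month) in self.data.index

    def year_values(self, year: int) -> pd.Series:
        """All stored months of a calendar year (may be fewer than 12)."""
        return self.data[self.data.index.year == year]

    def years(self) -> list[int]:
        return sorted(set(int(y) for y in self.data.index.year))

    def complete_years(self) -> list[int]:
        return [y for y in self.years() if len(self.year_values(y)) == 12]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with ``year``, ``month``, ``value`` columns."""
        idx = self.data.index
        return pd.DataFrame(
            {"year": idx.year, "month": idx.month, "value": self.data.to_numpy()}
        )

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class EmissionsSeries:
    """Annual total anthropogenic emissions (fossil fuel + land use), GtC/yr."""

    data: pd.Series  # indexed by integer calendar year

    def __post_init__(self):
        s = pd.Series(np.asarray(self.data, dtype=float), index=self.data.index)
        s.index = s.index.astype(int)
        if s.index.has_duplicates:
            raise InputFormatError("duplicate emission years")
        if (s < 0).any():
            raise InputFormatError("emissions must be non-negative")
        object.__setattr__(self, "data", s.sort_index())

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "EmissionsSeries":
        return cls(pd.Series(dict(mapping), dtype=float))

    def value(self, year: int) -> float:
        try:
            return float(self.data.loc[int(year)])
        except KeyError:
            raise MissingMonthsError(f"no emissions for year {year}", [(year, None)]) from None

    def years(self) -> list[int]:
        return [int(y) for y in self.data.index]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SeasonalCycle:
    """Twelve monthly adjustment factors (mean offset from the annual mean).

    The factors sum to zero by construction, so adding them to an annual
    mean produces monthly values whose average is that annual mean.
    """

    factors: np.ndarray
    reference_years: tuple[int, int] | None = None

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if f.shape != (12,):
            raise InputFormatError("SeasonalCycle needs exactly 12 factors")
        scale = max(1.0, float(np.max(np.abs(f))))
        if abs(f.sum()) > 1e-6 * scale:
            raise InputFormatError(f"factors must sum to 0, got {f.sum():g}")
        object.__setattr__(self, "factors", f)

    @classmethod
    def from_factors(cls, values: Sequence[float], reference_years=None) -> "SeasonalCycle":
        return cls(np.asarray(values, dtype=float), reference_years)

    @classmethod
    def with_month_factor(cls, month: int, value: float) -> "SeasonalCycle":
        """A minimal cycle carrying one month's factor, others compensating.

        Useful when only a single published adjustment factor is available
        and only that month's downscaled value is of interest.
        """
        f = np.full(12, -value / 11.0)
        f[month - 1] = value
        return cls(f)

    def factor(self, month: int) -> float:
        if not 1 <= month <= 12:
            raise InputFormatError(f"month must be in 1..12, got {month}")
        return float(self.factors[month - 1])


# ---------------------------------------------------------------------------
# annual statistics


def _year_months(series: MonthlySeries, year: int) -> tuple[list[float], list[tuple[int, int]]]:
    vals, missing = [], []
    for m in range(1, 13):
        if series.has(year, m):
            vals.append(series.value(year, m))
        else:
            missing.append((year, m))
    return vals, missing


def annual_mean(series: MonthlySeries, year: int, gap_policy: str = "strict") -> float:
    """Equal-weight mean of the 12 monthly values of a calendar year.

    gap_policy
        ``"strict"`` (default): any missing month is an error, named in the
        exception.  ``"interpolate_single"``: a single missing month is
        filled by averaging the two calendar-adjacent months (which may lie
        in neighbouring years); more than one gap is still an error.
    """
    vals, missing = _year_months(series, year)
    if not missing:
        return float(np.mean(vals))
    if gap_policy == "interpolate_single" and len(missing) == 1:
        (y, m), = missing
        prev_p = _period(y, m) - 1
        next_p = _period(y, m) + 1
        try:
            lo = series.value(prev_p.year, prev_p.month)
            hi = series.value(next_p.year, next_p.month)
        except MissingMonthsError:
            raise MissingMonthsError(
                f"cannot interpolate {y}-{m:02d}: neighbouring months absent", missing
            ) from None
        filled = vals + [(lo + hi) / 2.0]
        return float(np.mean(filled))
    names = ", ".join(f"{y}-{m:02d}" for y, m in missing)
    raise MissingMonthsError(f"year {year} incomplete; missing months: {names}", missing)


def annual_increment(series: MonthlySeries, year: int, gap_policy: str = "strict") -> float:
    """Annual-mean difference between ``year`` and ``year - 1`` (later-year indexed)."""
    return annual_mean(series, year, gap_policy) - annual_mean(series, year - 1, gap_policy)


def in_year_growth(series: MonthlySeries, year: int) -> float:
    """Concentration change across a calendar year.

    Convention: December(year) minus December(year-1) monthly means.  This
    single-month convention is deliberately isolated here so alternatives
    (e.g. multi-month boundary averaging) can replace it in one place.
    """
    return series.value(year, 12) - series.value(year - 1, 12)


def _resolve_years(reference_years) -> list[int]:
    if isinstance(reference_years, tuple) and len(reference_years) == 2:
        lo, hi = reference_years
        return list(range(int(lo), int(hi) + 1))
    return [int(y) for y in reference_years]


def seasonal_factors(series: MonthlySeries, reference_years) -> SeasonalCycle:
    """Mean monthly offsets from the annual mean over a reference year range.

    ``reference_years`` is either an inclusive ``(first, last)`` tuple or an
    iterable of years.  Every reference year must be complete.
    """
    years = _resolve_years(reference_years)
    if not years:
        raise InputFormatError("empty reference year range")
    offsets = np.zeros((len(years), 12))
    for i, y in enumerate(years):
        am = annual_mean(series, y)  # strict: raises if incomplete
        offsets[i] = [series.value(y, m) - am for m in range(1, 13)]
    factors = offsets.mean(axis=0)
    factors = factors - factors.mean()  # kill accumulated rounding; exact zero-sum
    return SeasonalCycle(factors, (min(years), max(years)))


def seasonal_amplitude_trend(series: MonthlySeries, min_years: int = 3) -> tuple[pd.Series, float]:
    """Per-year seasonal amplitude and its linear trend.

    Amplitude of a year is max minus min of its within-year monthly offsets
    (equivalently of its monthly values).  The trend is the slope of an
    ordinary straight-line fit of amplitude against year, in series units
    per year.  Requires at least ``min_years`` complete years.
    """
    years = series.complete_years()
    if len(years) < min_years:
        raise MissingMonthsError(
            f"need at least {min_years} complete years, found {len(years)}",
            [],
        )
    amps = pd.Series(
        {y: float(series.year_values(y).max() - series.year_values(y).min()) for y in years}
    )
    if amps.nunique() == 1:
        return amps, 0.0
    fit = stats.linregress(amps.index.to_numpy(dtype=float), amps.to_numpy())
    return amps, float(fit.slope)
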