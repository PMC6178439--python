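"""Forecast verification: interval hits and the long-run miss-rate calculus.

A forecast is stated as a central value with a +/- 2 s.d. range; a verifying
observation "hits" when it falls inside the range, boundary inclusive.  For
a well-calibrated Gaussian forecast the per-year probability of a miss is
1 minus the +/-2 s.d. normal mass (about 4.55%), so even a good forecast
system accumulates misses over the years: assuming independent, normally
distributed errors, the chance of at least one miss in k years is
1 - coverage**k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError


class IntervalCheck(NamedTuple):
    hit: bool
    error: float  # observed minus central, signed


def gaussian_coverage(n_sd: float = 2.0) -> float:
    """Probability mass of a Gaussian within +/- n_sd standard deviations."""
    return math.erf(n_sd / math.sqrt(2.0))


def verify_interval(central: float, two_sd: float, observed: float) -> IntervalCheck:
    """Hit/miss of an observation against a central +/- two_sd range.

    Ties at the boundary count as hits.
    """
    if two_sd < 0:
        raise InputFormatError("two_sd must be non-negative")
    error = observed - central
    return IntervalCheck(hit=abs(error) <= two_sd, error=float(error))


def monthly_hit_count(
    forecast_months: Sequence[float], two_sd: float, observed_months: Sequence[float]
) -> int:
    """How many of 12 monthly observations fall within the forecast range."""
    f = np.asarray(forecast_months, dtype=float)
    o = np.asarray(observed_months, dtype=float)
    if f.shape != (12,) or o.shape != (12,):
        raise InputFormatError("both monthly vectors must have length 12")
    return int(np.sum(np.abs(o - f) <= two_sd))


def miss_probability(k_years: int, coverage: float | None = None) -> float:
    """Probability of at least one miss over k independent forecast years.

    ``coverage`` defaults to the Gaussian +/-2 s.d. mass (~0.9545), i.e. a
    per-year miss chance of ~4.55% for a perfectly calibrated forecast.
    """
    if k_years < 0:
        raise InputFormatError("k_years must be non-negative")
    c = gaussian_coverage() if coverage is None else coverage
    if not 0.0 < c <= 1.0:
        raise InputFormatError("coverage must be in (0, 1]")
    return 1.0 - c**k_years


@dataclass
class VerificationReport:
    """Named interval checks plus an optional monthly hit count."""

    entries: list[tuple[str, float, float, float, bool, float]] = field(default_factory=list)
    monthly_hits: int | None = None

    def add(self, name: str, central: float, two_sd: float, observed: float) -> IntervalCheck:
        chk = verify_interval(central, two_sd, observed)
        self.entries.append((name, central, two_sd, observed, chk.hit, chk.error))
        return chk

    def add_monthly(
        self, forecast_months: Sequence[float], two_sd: float, observed_months: Sequence[float]
    ) -> int:
        self.monthly_hits = monthly_hit_count(forecast_months, two_sd, observed_months)
        return self.monthly_hits

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["quantity", "forecast", "two_sd", "observed", "hit", "error"],
        )

    def to_text(self) -> str:
        lines = ["forecast verification"]
        for name, central, two_sd, observed, hit, error in self.entries:
            tag = "HIT " if hit else "MISS"
            lines.append(
                f"  {tag} {name}: forecast {central:.2f} +/- {two_sd:.2f}, "
                f"observed {observed:.2f} (error {error:+.2f})"
            )
        if self.monthly_hits is not None:
            lines.append(f"  months within range: {self.monthly_hits}/12")
        return "\n".join(lines)
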