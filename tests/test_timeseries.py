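import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ninocast import (
    EmissionsSeries,
    MonthlySeries,
    SeasonalCycle,
    annual_increment,
    annual_mean,
    in_year_growth,
    seasonal_amplitude_trend,
    seasonal_factors,
)
from ninocast.errors import InputFormatError, MissingMonthsError

from conftest import flat_year, monthly


class TestAnnualMean:
    def test_constant_year(self):
        s = monthly(flat_year(2015, 400.0))
        assert annual_mean(s, 2015) == 400.0

    def test_months_one_to_twelve(self):
        s = monthly([(2000, m, float(m)) for m in range(1, 13)])
        assert annual_mean(s, 2000) == 6.5

    def test_corrected_forecast_arithmetic(self):
        # annual mean built from previous mean + increment: 400.89 + 3.28
        s = monthly(flat_year(2015, 400.89) + flat_year(2016, 400.89 + 3.28))
        assert round(annual_mean(s, 2016), 2) == 404.17

    def test_missing_month_named_in_error(self):
        records = [(2010, m, 1.0) for m in range(1, 13) if m != 7]
        with pytest.raises(MissingMonthsError) as exc:
            annual_mean(monthly(records), 2010)
        assert "2010-07" in str(exc.value)
        assert exc.value.missing == [(2010, 7)]

    def test_single_gap_interpolation(self):
        # linear ramp: interpolating the gap reproduces the complete-year mean
        full = [(2010, m, 100.0 + m) for m in range(1, 13)]
        gapped = [r for r in full if r[1] != 6]
        got = annual_mean(monthly(gapped), 2010, gap_policy="interpolate_single")
        assert got == pytest.approx(annual_mean(monthly(full), 2010))

    def test_two_gaps_rejected_even_when_interpolating(self):
        records = [(2010, m, 1.0) for m in range(1, 13) if m not in (3, 9)]
        with pytest.raises(MissingMonthsError):
            annual_mean(monthly(records), 2010, gap_policy="interpolate_single")

    @given(st.randoms(use_true_random=False))
    def test_invariant_under_record_order(self, rnd):
        records = [(2001, m, float(m) * 1.5 - 3) for m in range(1, 13)]
        shuffled = records[:]
        rnd.shuffle(shuffled)
        assert annual_mean(monthly(shuffled), 2001) == annual_mean(monthly(records), 2001)


class TestAnnualIncrement:
    def test_observed_2016_rise(self):
        s = monthly(flat_year(2015, 400.89) + flat_year(2016, 404.28))
        assert round(annual_increment(s, 2016), 2) == 3.39

    def test_1998_rise(self):
        s = monthly(flat_year(1997, 363.8) + flat_year(1998, 366.7))
        assert annual_increment(s, 1998) == pytest.approx(2.9)

    def test_identical_years_give_zero(self):
        s = monthly(flat_year(2000, 370.0) + flat_year(2001, 370.0))
        assert annual_increment(s, 2001) == 0.0

    def test_telescoping_sum(self):
        rng = np.random.default_rng(0)
        recs = []
        for k, y in enumerate(range(2000, 2007)):
            base = 370.0 + 2.0 * k
            recs += [(y, m, base + rng.normal(0, 1)) for m in range(1, 13)]
        s = monthly(recs)
        total = sum(annual_increment(s, y) for y in range(2001, 2007))
        assert total == pytest.approx(annual_mean(s, 2006) - annual_mean(s, 2000))


class TestInYearGrowth:
    def test_linear_ramp(self):
        rate = 2.4
        recs = [
            (y, m, 350.0 + rate * ((y - 2000) + (m - 1) / 12.0))
            for y in (2000, 2001)
            for m in range(1, 13)
        ]
        assert in_year_growth(monthly(recs), 2001) == pytest.approx(rate)

    def test_flat_series(self):
        s = monthly(flat_year(2000, 400.0) + flat_year(2001, 400.0))
        assert in_year_growth(s, 2001) == 0.0

    def test_mid_year_step_fully_counted(self):
        step = 1.7
        recs = flat_year(2000, 390.0) + [
            (2001, m, 390.0 + (step if m >= 7 else 0.0)) for m in range(1, 13)
        ]
        assert in_year_growth(monthly(recs), 2001) == pytest.approx(step)

    def test_missing_boundary_month(self):
        recs = flat_year(2000, 390.0) + [(2001, m, 391.0) for m in range(1, 12)]
        with pytest.raises(MissingMonthsError):
            in_year_growth(monthly(recs), 2001)


class TestSeasonalFactors:
    @staticmethod
    def _sinusoid_series(years, amplitude=3.0, trend=0.0):
        recs = []
        for y in years:
            for m in range(1, 13):
                recs.append(
                    (y, m, 400.0 + trend * (y - years[0]) + amplitude * math.sin(2 * math.pi * m / 12))
                )
        return monthly(recs)

    def test_sinusoid_recovered(self):
        s = self._sinusoid_series([2000, 2001, 2002])
        cyc = seasonal_factors(s, (2000, 2002))
        expected = [3.0 * math.sin(2 * math.pi * m / 12) for m in range(1, 13)]
        assert np.allclose(cyc.factors, expected)

    def test_constant_series_gives_zero_factors(self):
        s = monthly(flat_year(2000, 400.0) + flat_year(2001, 400.0))
        assert np.allclose(seasonal_factors(s, (2000, 2001)).factors, 0.0)

    def test_factors_sum_to_zero(self):
        s = self._sinusoid_series(range(1995, 2005), trend=2.1)
        assert seasonal_factors(s, (1995, 2004)).factors.sum() == pytest.approx(0.0, abs=1e-12)

    def test_stationary_cycle_reconstructs_series(self):
        s = self._sinusoid_series(range(2000, 2004), trend=2.0)
        cyc = seasonal_factors(s, (2000, 2003))
        for y in range(2000, 2004):
            am = annual_mean(s, y)
            rebuilt = am + cyc.factors
            assert np.allclose(rebuilt, [s.value(y, m) for m in range(1, 13)])

    def test_incomplete_reference_year_rejected(self):
        s = monthly(flat_year(2000, 1.0) + [(2001, 1, 1.0)])
        with pytest.raises(MissingMonthsError):
            seasonal_factors(s, (2000, 2001))

    def test_empty_reference_range_rejected(self):
        s = monthly(flat_year(2000, 1.0))
        with pytest.raises(InputFormatError):
            seasonal_factors(s, [])


class TestSeasonalAmplitudeTrend:
    def test_stationary_cycle_has_near_zero_slope(self):
        s = TestSeasonalFactors._sinusoid_series(range(2000, 2010), trend=2.0)
        amps, slope = seasonal_amplitude_trend(s)
        assert np.allclose(amps, 6.0)
        assert slope == 0.0

    def test_constructed_growth_recovered(self):
        rate = 0.05  # ppm of extra peak-to-trough per year
        s = monthly(
            [
                (y, m, 400.0 + ((6.0 + rate * (y - 2000)) / 2.0) * math.cos(2 * math.pi * (m - 5) / 12))
                for y in range(2000, 2012)
                for m in range(1, 13)
            ]
        )
        amps, slope = seasonal_amplitude_trend(s)
        # sampled cosine max-min equals peak-to-trough here (month 5 and 11 hit the extremes)
        assert slope == pytest.approx(rate, rel=1e-9)

    def test_too_few_years_rejected(self):
        s = monthly(flat_year(2000, 1.0) + flat_year(2001, 1.0))
        with pytest.raises(MissingMonthsError):
            seasonal_amplitude_trend(s)


class TestContainers:
    def test_duplicate_months_rejected(self):
        with pytest.raises(InputFormatError):
            monthly([(2000, 1, 1.0), (2000, 1, 2.0)])

    def test_bad_month_rejected(self):
        with pytest.raises(InputFormatError):
            monthly([(2000, 13, 1.0)])

    def test_nonfinite_rejected(self):
        with pytest.raises(InputFormatError):
            monthly([(2000, 1, float("nan"))])

    def test_negative_emissions_rejected(self):
        with pytest.raises(InputFormatError):
            EmissionsSeries.from_mapping({2000: -1.0})

    def test_seasonal_cycle_must_sum_to_zero(self):
        with pytest.raises(InputFormatError):
            SeasonalCycle.from_factors([1.0] * 12)

    def test_with_month_factor_carries_value(self):
        cyc = SeasonalCycle.with_month_factor(9, -2.97)
        assert cyc.factor(9) == pytest.approx(-2.97)
        assert cyc.factors.sum() == pytest.approx(0.0, abs=1e-12)
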