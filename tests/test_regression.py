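import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ninocast import (
    DesignRow,
    IncrementModel,
    MonthlySeries,
    SeasonalCycle,
    build_design_rows,
    calibrate,
    forecast_concentrations,
    predict_increment,
    reconstruct_history,
)
from ninocast.regression import load_model, save_model
from ninocast.timeseries import EmissionsSeries
from ninocast.errors import InputFormatError, RankDeficientError

from conftest import flat_year, monthly

ALPHAS_PUBLISHED = (-0.132, 0.415, 0.237)


def synthetic_rows(alphas, n=20, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a1, a2, a3 = alphas
    rows = []
    for k in range(n):
        nino = rng.normal(0.0, 0.8)
        eps = 5.0 + 0.1 * k + rng.normal(0, 0.2)
        d = a1 + a2 * nino + a3 * eps + rng.normal(0, noise_sd)
        rows.append(DesignRow(1960 + k, d, nino, eps))
    return rows


class TestCalibrate:
    def test_noiseless_recovery_is_exact(self):
        rows = synthetic_rows(ALPHAS_PUBLISHED, n=12)
        model = calibrate(rows)
        assert model.alphas == pytest.approx(ALPHAS_PUBLISHED, abs=1e-10)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert model.n_rows == 12

    def test_matches_statsmodels_on_noisy_rows(self):
        sm = pytest.importorskip("statsmodels.api")
        rows = synthetic_rows(ALPHAS_PUBLISHED, n=40, noise_sd=0.3, seed=2)
        model = calibrate(rows)
        X = np.array([[1.0, r.nino, r.emissions_prev] for r in rows])
        y = np.array([r.delta_co2 for r in rows])
        fit = sm.OLS(y, X).fit()
        assert model.alphas == pytest.approx(tuple(fit.params), abs=1e-9)
        assert model.alpha_se == pytest.approx(tuple(fit.bse), abs=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputFormatError):
            calibrate(synthetic_rows(ALPHAS_PUBLISHED, n=3))

    def test_collinear_predictors_reported(self):
        rows = [DesignRow(1960 + k, 2.0, 1.0, 8.0) for k in range(6)]
        with pytest.raises(RankDeficientError):
            calibrate(rows)

    def test_excluded_years_dropped(self):
        rows = synthetic_rows(ALPHAS_PUBLISHED, n=12)
        spoiled = rows + [DesignRow(1999, 99.0, 0.0, 8.0)]
        model = calibrate(spoiled, excluded_years=[1999])
        assert model.alphas == pytest.approx(ALPHAS_PUBLISHED, abs=1e-10)

    @pytest.mark.parametrize("n", [20, 56, 200])
    def test_estimator_concentrates_with_sample_size(self, n):
        ests = []
        for rep in range(60):
            rows = synthetic_rows(ALPHAS_PUBLISHED, n=n, noise_sd=0.25, seed=1000 + rep)
            ests.append(calibrate(rows).alpha2)
        bias = abs(np.mean(ests) - ALPHAS_PUBLISHED[1])
        # spread and bias must shrink roughly like 1/sqrt(n)
        assert bias < 3.0 * 0.25 / np.sqrt(n)


class TestPredictIncrement:
    def test_published_forecast_value(self):
        model = IncrementModel(*ALPHAS_PUBLISHED, fixed_two_sd=0.53)
        inc, two_sd = predict_increment(model, 2.02, 10.3)
        assert round(inc, 2) == 3.15
        assert two_sd == 0.53

    def test_corrected_forecast_value(self):
        model = IncrementModel(*ALPHAS_PUBLISHED)
        inc, _ = predict_increment(model, 2.02, 10.84)
        assert round(inc, 2) == 3.28

    def test_intercept_at_zero_inputs(self):
        model = IncrementModel(0.7, 0.4, 0.2)
        assert predict_increment(model, 0.0, 0.0)[0] == pytest.approx(0.7)

    def test_nonfinite_inputs_rejected(self):
        model = IncrementModel(*ALPHAS_PUBLISHED)
        with pytest.raises(InputFormatError):
            predict_increment(model, float("nan"), 10.0)

    @given(
        st.floats(-2, 2).map(lambda v: round(v, 3)),
        st.floats(0, 12).map(lambda v: round(v, 3)),
        st.floats(0.5, 1.5).map(lambda v: round(v, 3)),
    )
    def test_affine_finite_differences_recover_sensitivities(self, nino, eps, h):
        model = IncrementModel(0.045, 0.426, 0.214)
        f = lambda n, e: predict_increment(model, n, e)[0]
        assert (f(nino + h, eps) - f(nino, eps)) / h == pytest.approx(model.alpha2)
        assert (f(nino, eps + h) - f(nino, eps)) / h == pytest.approx(model.alpha3)


class TestReconstruction:
    def test_ols_residuals_average_to_zero(self):
        rows = synthetic_rows(ALPHAS_PUBLISHED, n=30, noise_sd=0.4, seed=5)
        model = calibrate(rows)
        fitted = reconstruct_history(model, rows)
        resid = np.array([r.delta_co2 for r in rows]) - fitted.to_numpy()
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_reconstruction_equals_truth(self):
        rows = synthetic_rows(ALPHAS_PUBLISHED, n=15)
        model = calibrate(rows)
        fitted = reconstruct_history(model, rows)
        assert fitted.to_numpy() == pytest.approx([r.delta_co2 for r in rows])

    def test_enso_term_adds_reconstruction_skill(self):
        # paired Monte-Carlo: full model vs emissions-only on fresh noise
        wins = 0
        for rep in range(40):
            rows = synthetic_rows(ALPHAS_PUBLISHED, n=40, noise_sd=0.25, seed=300 + rep)
            truth = np.array([r.delta_co2 for r in rows])
            model = calibrate(rows)
            full = reconstruct_history(model, rows).to_numpy()
            X = np.array([[1.0, r.emissions_prev] for r in rows])
            beta, *_ = np.linalg.lstsq(X, truth, rcond=None)
            reduced = X @ beta
            if np.corrcoef(full, truth)[0, 1] > np.corrcoef(reduced, truth)[0, 1]:
                wins += 1
        assert wins >= 36  # ENSO carries real signal in nearly every replicate


class TestBuildDesignRows:
    def test_rows_match_generator_bookkeeping(self, noiseless_bundle):
        b = noiseless_bundle
        years = range(1990, 2011)
        rows = build_design_rows(b.co2, b.truth.nino_window, b.emissions, years)
        assert [r.year for r in rows] == list(years)
        for r in rows:
            assert r.delta_co2 == pytest.approx(b.truth.increments[r.year], abs=1e-9)
            assert r.nino == pytest.approx(b.truth.nino_window[r.year])
            assert r.emissions_prev == pytest.approx(b.emissions.value(r.year - 1))

    def test_unresolvable_years_dropped(self):
        co2 = monthly(flat_year(1999, 368.0) + flat_year(2000, 370.0) + flat_year(2001, 372.0))
        emissions = EmissionsSeries.from_mapping({1999: 6.5, 2000: 6.6})
        nino = {2000: 0.5, 2001: 0.2}
        rows = build_design_rows(co2, nino, emissions, range(1998, 2003))
        assert [r.year for r in rows] == [2000, 2001]

    def test_empty_row_set_rejected(self):
        co2 = monthly(flat_year(2000, 370.0))
        emissions = EmissionsSeries.from_mapping({2000: 6.6})
        with pytest.raises(InputFormatError):
            build_design_rows(co2, {}, emissions, [2001])


class TestForecastConcentrations:
    def test_corrected_2016_annual_mean(self):
        cycle = SeasonalCycle.from_factors(np.zeros(12))
        res = forecast_concentrations(400.89, 3.28, cycle, target_year=2016)
        assert round(res.annual_mean, 2) == 404.17

    def test_observed_2016_annual_mean(self):
        cycle = SeasonalCycle.from_factors(np.zeros(12))
        res = forecast_concentrations(400.89, 3.39, cycle)
        assert round(res.annual_mean, 2) == 404.28

    def test_zero_factors_give_flat_months(self):
        cycle = SeasonalCycle.from_factors(np.zeros(12))
        res = forecast_concentrations(400.0, 2.0, cycle)
        assert np.allclose(res.monthly_means, 402.0)

    def test_monthly_means_average_to_annual(self):
        cycle = SeasonalCycle.with_month_factor(5, 3.1)
        res = forecast_concentrations(400.0, 2.5, cycle)
        assert res.monthly_means.mean() == pytest.approx(res.annual_mean)

    def test_components_must_sum_to_increment(self):
        cycle = SeasonalCycle.from_factors(np.zeros(12))
        with pytest.raises(InputFormatError):
            forecast_concentrations(400.0, 2.0, cycle, components=(1.0, 0.2, 0.3))


class TestSerialization:
    def test_round_trip(self, tmp_path):
        model = IncrementModel(
            0.045, 0.426, 0.214,
            residual_sd=0.26,
            calibration_years=(1959, 2014),
            n_rows=56,
            alpha_se=(0.3, 0.05, 0.03),
            fixed_two_sd=0.53,
        )
        path = tmp_path / "model.txt"
        save_model(model, path)
        back = load_model(path)
        assert back == model
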