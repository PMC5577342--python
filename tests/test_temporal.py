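"""Autoregressive trend machinery: correlograms, order selection,
conditional-least-squares fitting, residual diagnostics, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg, stats

import rhinocast as rc
from rhinocast.errors import (DegenerateSeriesError, EstimationError,
                              InvalidParameterError)


# --------------------------------------------------------------- oracles

def brute_acf(x, max_lag):
    """Divide-by-n sample ACF straight from the definition."""
    x = np.asarray(x, float)
    n = x.size
    d = x - x.mean()
    c = [np.sum(d[k:] * d[:n - k]) / n for k in range(max_lag + 1)]
    return np.array(c) / c[0]


def brute_pacf(x, max_lag):
    """PACF via explicit Yule-Walker solves of orders 1..max_lag."""
    rho = brute_acf(x, max_lag)
    out = [1.0]
    for m in range(1, max_lag + 1):
        R = linalg.toeplitz(rho[:m])
        phi = np.linalg.solve(R, rho[1:m + 1])
        out.append(phi[-1])
    return np.array(out)


# --------------------------------------------------------------- acf

class TestAcf:
    def test_lag_zero_is_one_and_values_bounded(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        a = rc.acf(x, 20)
        assert a[0] == 1.0
        assert np.all(np.abs(a) <= 1.0 + 1e-12)

    def test_six_point_hand_computation(self):
        # for [1..6]: lag-1 autocovariance ratio is 8.75/17.5 = 0.5
        assert rc.acf([1, 2, 3, 4, 5, 6], 1)[1] == pytest.approx(0.5, abs=1e-12)

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateSeriesError):
            rc.acf([5.0] * 50, 3)

    def test_too_short_series_raises(self):
        with pytest.raises(InvalidParameterError):
            rc.acf([1.0, 2.0, 3.0], 3)

    def test_null_band_on_iid_noise(self):
        """For iid noise, |acf[k]| stays below 4/sqrt(n) at lags 1..10
        in at least 99 of 100 seeds (asymptotic null band)."""
        n = 10_000
        band = 4.0 / np.sqrt(n)
        ok = 0
        for s in range(100):
            x = np.random.default_rng(s).normal(size=n)
            ok += bool(np.all(np.abs(rc.acf(x, 10)[1:]) < band))
        assert ok >= 99


# --------------------------------------------------------------- pacf

class TestPacf:
    def test_lag_one_equals_acf_lag_one(self):
        x = np.random.default_rng(1).normal(size=200).cumsum()
        assert rc.pacf(x, 5)[1] == pytest.approx(rc.acf(x, 5)[1], abs=1e-12)

    def test_matches_yule_walker_oracle_on_six_points(self):
        x = [1, 2, 3, 4, 5, 6]
        np.testing.assert_allclose(rc.pacf(x, 3), brute_pacf(x, 3),
                                   atol=1e-10)

    def test_ar1_cutoff(self):
        """For an AR(1) process the PACF beyond lag 1 sits inside the
        4/sqrt(n) null band in >= 95 of 100 seeds."""
        model = rc.ARModel((1,), (0.7,))
        n = 5_000
        band = 4.0 / np.sqrt(n)
        ok = 0
        for s in range(100):
            x = rc.simulate_ar(model, n, seed=s)
            ok += bool(np.all(np.abs(rc.pacf(x, 6)[2:]) < band))
        assert ok >= 95


@settings(max_examples=150, deadline=None)
@given(data=st.lists(st.integers(min_value=0, max_value=5),
                     min_size=4, max_size=8))
def test_correlograms_match_brute_force_on_small_series(data):
    """ACF/PACF agree with from-scratch oracles on every small integer
    series (sampled over length <= 8, entries 0..5)."""
    x = np.array(data, float)
    if np.ptp(x) == 0:
        with pytest.raises(DegenerateSeriesError):
            rc.acf(x, 1)
        return
    max_lag = min(2, len(x) - 2)
    if max_lag < 1:
        return
    np.testing.assert_allclose(rc.acf(x, max_lag), brute_acf(x, max_lag),
                               atol=1e-10)
    try:
        mine = rc.pacf(x, max_lag)
    except DegenerateSeriesError:
        return  # non-PD sample autocorrelation: oracle would divide by ~0
    np.testing.assert_allclose(mine, brute_pacf(x, max_lag), atol=1e-8)


def test_correlograms_match_statsmodels():
    """Independent library cross-check of both conventions."""
    sm = pytest.importorskip("statsmodels.api")
    x = rc.simulate_ar(rc.ARModel((1, 4), (0.5, -0.2)), 500, seed=7)
    np.testing.assert_allclose(
        rc.acf(x, 12), sm.tsa.stattools.acf(x, nlags=12, adjusted=False, fft=False),
        atol=1e-10)
    np.testing.assert_allclose(
        rc.pacf(x, 12), sm.tsa.stattools.pacf(x, nlags=12, method="ldb"),
        atol=1e-10)


# --------------------------------------------------------------- order selection

class TestSelectOrder:
    def test_single_cell_grid(self):
        x = np.random.default_rng(0).normal(size=100)
        assert rc.select_order(x, 0, 0) == (0, 0)

    def test_recovers_ar1(self):
        model = rc.ARModel((1,), (0.8,))
        hits = sum(rc.select_order(rc.simulate_ar(model, 2000, seed=s), 3, 3)
                   == (1, 0) for s in range(100))
        assert hits >= 90

    def test_white_noise_selects_empty_model(self):
        hits = sum(rc.select_order(np.random.default_rng(s).normal(size=2000),
                                   3, 3) == (0, 0) for s in range(100))
        assert hits > 50

    def test_bic_drops_when_true_lag_added(self):
        """Adding the true second lag to an underfit AR(1) model lowers
        the in-sample residual variance enough to beat the BIC penalty
        in >= 90 of 100 seeds."""
        model = rc.ARModel((1, 2), (0.5, 0.3))
        n = 1000
        hits = 0
        for s in range(100):
            x = rc.simulate_ar(model, n, seed=s)
            sd1 = rc.fit_ar(x, (1,)).innovation_sd
            sd2 = rc.fit_ar(x, (1, 2)).innovation_sd
            bic1 = n * np.log(sd1 ** 2) + 1 * np.log(n)
            bic2 = n * np.log(sd2 ** 2) + 2 * np.log(n)
            hits += bic2 < bic1
        assert hits >= 90

    def test_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            rc.select_order(np.arange(30.0), 3, 3)


# --------------------------------------------------------------- fit_ar

class TestFitAr:
    def test_exact_recovery_of_noiseless_recursion(self):
        x = 100.0 * 0.5 ** np.arange(50)
        fit = rc.fit_ar(x, (1,), demean=False)
        assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("lags, phi", [
        ((1,), (0.73918,)),            # mould trend
        ((1, 2), (0.92557, -0.27506)),  # dust-mite trend
        ((1, 4), (0.83473, -0.21551)),  # pollen trend (sparse lags)
    ])
    def test_recovers_trend_coefficients_from_long_simulation(self, lags, phi):
        model = rc.ARModel(lags, phi, innovation_sd=1.0)
        x = rc.simulate_ar(model, 100_000, burn_in=1000, seed=42)
        fit = rc.fit_ar(x, lags)
        for est, true in zip(fit.coefficients, phi):
            assert est == pytest.approx(true, abs=0.01)

    def test_convergence_rate(self):
        """Estimation error shrinks roughly as 1/sqrt(n)."""
        model = rc.ARModel((1, 3), (0.6, -0.25))
        errs = []
        for n in (1_000, 10_000, 100_000):
            x = rc.simulate_ar(model, n, seed=5)
            fit = rc.fit_ar(x, (1, 3))
            errs.append(max(abs(e - t) for e, t in
                            zip(fit.coefficients, model.coefficients)))
        assert errs[2] < errs[0]
        assert errs[2] < 5e-3

    def test_mean_is_stored_and_series_demeaned(self):
        model = rc.ARModel((1,), (0.6,), series_mean=50.0, innovation_sd=2.0)
        x = rc.simulate_ar(model, 20_000, seed=3)
        fit = rc.fit_ar(x, (1,))
        assert fit.series_mean == pytest.approx(50.0, abs=1.0)
        assert fit.coefficients[0] == pytest.approx(0.6, abs=0.03)
        assert fit.innovation_sd == pytest.approx(2.0, rel=0.05)

    def test_constant_series_is_singular(self):
        with pytest.raises(EstimationError):
            rc.fit_ar(np.full(100, 7.0), (1,))

    def test_model_invariants(self):
        with pytest.raises(InvalidParameterError):
            rc.ARModel((1, 2), (0.5,))
        with pytest.raises(InvalidParameterError):
            rc.ARModel((0,), (0.5,))
        assert rc.ARModel((1,), (0.99,)).is_stationary
        assert not rc.ARModel((1,), (1.01,)).is_stationary


# --------------------------------------------------------------- white noise

class TestWhiteNoiseTest:
    def test_type_i_error_calibration(self):
        """Rejection rate at alpha=0.05 on iid normal residuals lies in
        0.05 +- 0.02 over 1000 replicates."""
        rej = 0
        for s in range(1000):
            r = np.random.default_rng(s).normal(size=1000)
            rej += rc.white_noise_test(r, 10).p_value < 0.05
        assert 0.03 <= rej / 1000 <= 0.07

    def test_power_against_strong_autocorrelation(self):
        x = rc.simulate_ar(rc.ARModel((1,), (0.9,)), 500, seed=11)
        assert rc.white_noise_test(x, 10).p_value < 1e-3

    def test_all_zero_residuals_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            rc.white_noise_test(np.zeros(100), 5)

    def test_lag_count_contract(self):
        with pytest.raises(InvalidParameterError):
            rc.white_noise_test(np.random.default_rng(0).normal(size=10), 10)

    def test_dof_adjustment(self):
        r = np.random.default_rng(4).normal(size=200)
        full = rc.white_noise_test(r, 10)
        adj = rc.white_noise_test(r, 10, model_df=2)
        assert full.dof == 10 and adj.dof == 8
        assert adj.statistic == pytest.approx(full.statistic)

    def test_matches_statsmodels_ljung_box(self):
        smd = pytest.importorskip("statsmodels.stats.diagnostic")
        r = np.random.default_rng(9).normal(size=400)
        mine = rc.white_noise_test(r, 12)
        ref = smd.acorr_ljungbox(r, lags=[12])
        assert mine.statistic == pytest.approx(float(ref.lb_stat.iloc[0]), rel=1e-10)
        assert mine.p_value == pytest.approx(float(ref.lb_pvalue.iloc[0]), rel=1e-10)


# --------------------------------------------------------------- simulation

class TestSimulateAr:
    def test_null_model_is_iid_gaussian(self):
        model = rc.ARModel((1,), (0.0,), innovation_sd=3.0)
        x = rc.simulate_ar(model, 100_000, seed=0)
        assert np.std(x) == pytest.approx(3.0, rel=0.02)

    def test_ar1_theoretical_lag1_acf(self):
        model = rc.ARModel((1,), (0.8,))
        x = rc.simulate_ar(model, 100_000, seed=1)
        assert rc.acf(x, 1)[1] == pytest.approx(0.8, abs=0.01)

    def test_seed_determinism(self):
        model = rc.ARModel((1, 4), (0.5, -0.2))
        a = rc.simulate_ar(model, 500, seed=123)
        b = rc.simulate_ar(model, 500, seed=123)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, rc.simulate_ar(model, 500, seed=124))

    def test_nonstationary_model_rejected(self):
        with pytest.raises(InvalidParameterError):
            rc.simulate_ar(rc.ARModel((1,), (1.1,)), 100)

    def test_burn_in_floor_enforced(self):
        with pytest.raises(InvalidParameterError):
            rc.simulate_ar(rc.ARModel((1,), (0.5,)), 100, burn_in=3)
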