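"""Tests of the stage-1 seasonal models: temperature lagging, the state-space
machinery against a dense joint-Gaussian oracle, static/dynamic fits, lag
selection and the temperature-anomaly partition identity."""

import numpy as np
import pandas as pd
import pytest

from dhrpanel import (
    DynamicHarmonicRegression,
    StaticHarmonicRegression,
    build_state_space,
    gen_temperature,
    goodness_of_fit,
    kalman_filter,
    kalman_smooth,
    lag_temperature,
    select_lag,
    temperature_anomaly_identity,
)
from dhrpanel.kalman import OMEGA

from _oracles import dense_dhr, normal_equations_ols

ANCHOR = "2002-01-01"


# ---------------------------------------------------------------------------
# temperature lagging
# ---------------------------------------------------------------------------

class TestLagTemperature:
    def test_zero_lag_is_calendar_month_mean(self):
        daily = gen_temperature(6, seed=1, anchor=ANCHOR)
        got = lag_temperature(daily, 0, anchor=ANCHOR, n_months=6)
        expect = daily[daily.index >= ANCHOR].resample("MS").mean().to_numpy()[:6]
        np.testing.assert_allclose(got.to_numpy(), expect, rtol=1e-12)

    @pytest.mark.parametrize("lag", [0, 7, 14, 21, "1m"])
    def test_constant_series_invariant(self, lag):
        idx = pd.date_range("2001-11-01", "2002-12-31", freq="D")
        daily = pd.Series(3.25, index=idx)
        got = lag_temperature(daily, lag, anchor=ANCHOR, n_months=12)
        np.testing.assert_allclose(got.to_numpy(), 3.25)

    def test_linear_ramp_shifts_by_lag_times_slope(self):
        idx = pd.date_range("2001-11-01", "2002-12-31", freq="D")
        slope = 0.125
        daily = pd.Series(slope * np.arange(len(idx)), index=idx)
        m0 = lag_temperature(daily, 0, anchor=ANCHOR, n_months=12)
        m7 = lag_temperature(daily, 7, anchor=ANCHOR, n_months=12)
        np.testing.assert_allclose(m0.to_numpy() - m7.to_numpy(), 7 * slope, rtol=1e-12)

    def test_one_month_lag_is_previous_month_mean(self):
        idx = pd.date_range("2001-12-01", "2002-06-30", freq="D")
        daily = pd.Series(np.arange(len(idx), dtype=float), index=idx)
        got = lag_temperature(daily, "1m", anchor=ANCHOR, n_months=6)
        m0 = lag_temperature(daily, 0, anchor="2001-12-01", n_months=6)
        np.testing.assert_allclose(got.to_numpy()[:6], m0.to_numpy()[:6])

    def test_insufficient_coverage_masks_and_warns(self):
        idx = pd.date_range(ANCHOR, "2002-12-31", freq="D")  # no lead-in days
        daily = pd.Series(1.0 * np.arange(len(idx)), index=idx)
        with pytest.warns(UserWarning, match="lack full daily coverage"):
            got = lag_temperature(daily, 7, anchor=ANCHOR, n_months=12)
        assert np.isnan(got.iloc[0]) and np.isfinite(got.iloc[1:]).all()


# ---------------------------------------------------------------------------
# state space construction and Kalman recursions
# ---------------------------------------------------------------------------

class TestStateSpace:
    def test_state_dimension(self):
        ss = build_state_space(1, temperature=np.zeros(12), rw_variance=0.1, obs_variance=1.0)
        assert ss.dim == 4  # a, beta, A1, B1
        ss2 = build_state_space(3, n_months=12, rw_variance=0.1, obs_variance=1.0)
        assert ss2.dim == 7  # no temperature: 2k + 1

    def test_observation_vector_march(self):
        d = np.arange(1.0, 13.0)
        ss = build_state_space(1, temperature=d, rw_variance=0.1, obs_variance=1.0)
        np.testing.assert_allclose(ss.Z[2], [1.0, 3.0, np.cos(np.pi / 2), 1.0], atol=1e-15)
        assert abs(ss.Z[2][2]) < 1e-15  # cos(pi/2) = 0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            build_state_space(1, n_months=12, rw_variance=-0.1, obs_variance=1.0)
        with pytest.raises(ValueError):
            build_state_space(1, n_months=12, rw_variance=0.1, obs_variance=-1.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            build_state_space(6, n_months=24, rw_variance=0.0, obs_variance=1.0)


class TestKalmanOracle:
    @pytest.mark.parametrize("T,k,q,h", [(12, 1, 0.05, 0.3), (18, 2, 0.01, 0.1), (24, 1, 0.2, 1.0)])
    def test_loglik_and_smoother_match_dense_mvn(self, T, k, q, h, rng):
        d = 9.5 - 6.5 * np.cos(OMEGA * np.arange(1, T + 1)) + rng.normal(0, 1, T)
        y = rng.normal(0, 1, T).cumsum() * 0.1 + 0.2 * d
        ss = build_state_space(k, temperature=d, rw_variance=q, obs_variance=h, diffuse_var=1e7 * y.var())
        f = kalman_smooth(ss, y)
        ll_o, sm_o = dense_dhr(ss.Z, ss.Q, h, ss.P0, y)
        assert abs(f["loglik"] - ll_o) / max(1.0, abs(ll_o)) < 1e-6
        np.testing.assert_allclose(f["smoothed_mean"], sm_o, atol=1e-6 * (1 + np.abs(sm_o).max()))

    def test_loglik_with_missing_months(self, rng):
        T = 16
        d = rng.normal(10, 2, T)
        y = rng.normal(0, 1, T)
        y[[3, 8]] = np.nan
        ss = build_state_space(1, temperature=d, rw_variance=0.05, obs_variance=0.5, diffuse_var=1e6)
        f = kalman_smooth(ss, y)
        ll_o, sm_o = dense_dhr(ss.Z, ss.Q, 0.5, ss.P0, y)
        assert abs(f["loglik"] - ll_o) / max(1.0, abs(ll_o)) < 1e-6
        np.testing.assert_allclose(f["smoothed_mean"], sm_o, atol=1e-5)
        assert np.isfinite(f["fitted"]).all()  # fitted values exist at gaps

    def test_smoother_boundary_and_variance_reduction(self, rng):
        T = 20
        d = rng.normal(10, 2, T)
        y = rng.normal(0, 1, T)
        ss = build_state_space(1, temperature=d, rw_variance=0.1, obs_variance=0.4, diffuse_var=1e6)
        f = kalman_smooth(ss, y)
        np.testing.assert_allclose(f["smoothed_mean"][-1], f["filtered_mean"][-1], rtol=1e-12)
        sm_var = np.diagonal(f["smoothed_cov"], axis1=1, axis2=2)
        fi_var = np.diagonal(f["filtered_cov"], axis1=1, axis2=2)
        assert np.all(sm_var <= fi_var + 1e-8)

    def test_noiseless_constant_states_give_zero_innovations(self):
        T, k = 30, 1
        t = np.arange(1, T + 1)
        d = 9.5 - 6.5 * np.cos(OMEGA * t)
        y = 2.0 + 0.1 * d + 0.5 * np.cos(OMEGA * t) - 0.3 * np.sin(OMEGA * t)
        ss = build_state_space(k, temperature=d, rw_variance=0.0, obs_variance=1e-4, diffuse_var=1e8)
        f = kalman_filter(ss, y)
        dim = ss.dim
        assert np.nanmax(np.abs(f["innovations"][dim:])) < 1e-6

    def test_all_missing_rejected(self):
        ss = build_state_space(1, n_months=10, rw_variance=0.1, obs_variance=1.0)
        with pytest.raises(ValueError):
            kalman_filter(ss, np.full(10, np.nan))


class TestStaticLimit:
    def test_zero_rw_variance_reproduces_ols(self, rng):
        """With all random-walk variances at 0 the smoothed fit equals the
        static OLS harmonic regression."""
        T = 40
        t = np.arange(1, T + 1)
        d = 9.5 - 6.5 * np.cos(OMEGA * t) + rng.normal(0, 1.5, T)
        y = -2 + 0.05 * d + 0.2 * np.cos(OMEGA * t) + rng.normal(0, 0.1, T)
        ss = build_state_space(2, temperature=d, rw_variance=0.0, obs_variance=0.01, diffuse_var=1e7 * y.var())
        f = kalman_smooth(ss, y)
        stat = StaticHarmonicRegression(k=2).fit(d, y)
        # smoothed states constant over time
        assert np.abs(np.diff(f["smoothed_mean"], axis=0)).max() < 1e-6
        np.testing.assert_allclose(f["fitted"], stat.fitted_values_, atol=1e-6)


# ---------------------------------------------------------------------------
# static harmonic regression
# ---------------------------------------------------------------------------

class TestStaticHarmonic:
    def test_noiseless_recovery(self):
        T = 48
        t = np.arange(1, T + 1)
        d = 8.0 - 5.0 * np.cos(OMEGA * t) + np.sin(0.7 * t)
        y = 1.5 - 0.07 * d + 0.4 * np.cos(OMEGA * t) - 0.2 * np.sin(OMEGA * t)
        m = StaticHarmonicRegression(k=1).fit(d, y)
        np.testing.assert_allclose(
            m.coef_.to_numpy(), [1.5, -0.07, 0.4, -0.2], atol=1e-10
        )

    def test_intercept_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 7.0] * 4)
        m = StaticHarmonicRegression(k=1, include_temperature=False).fit(None, y)
        # harmonics orthogonal-ish; compare against normal-equations oracle
        t = np.arange(1, len(y) + 1)
        D = np.column_stack([np.ones_like(t, dtype=float), np.cos(OMEGA * t), np.sin(OMEGA * t)])
        np.testing.assert_allclose(m.coef_.to_numpy(), normal_equations_ols(D, y), atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        T = 60
        d = rng.normal(10, 3, T)
        y = rng.normal(0, 1, T)
        m = StaticHarmonicRegression(k=2).fit(d, y)
        t = np.arange(1, T + 1)
        D = np.column_stack(
            [np.ones(T), d]
            + [f(p * OMEGA * t) for p in (1, 2) for f in (np.cos, np.sin)]
        )
        np.testing.assert_allclose(m.coef_.to_numpy(), normal_equations_ols(D, y), atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        T = 24
        d = np.full(T, 7.0)  # constant temperature collinear with intercept
        y = np.random.default_rng(0).normal(size=T)
        with pytest.raises(ValueError, match="collinear"):
            StaticHarmonicRegression(k=1).fit(d, y)


class TestGoodnessOfFit:
    def test_perfect_and_orthogonal(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert goodness_of_fit(y, y) == pytest.approx(1.0)
        assert goodness_of_fit([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_oracle(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        fit = np.array([1.0, 2.0, 3.0, 5.0])
        num = np.sum((obs - obs.mean()) * (fit - fit.mean()))
        den = np.sqrt(np.sum((obs - obs.mean()) ** 2) * np.sum((fit - fit.mean()) ** 2))
        assert goodness_of_fit(obs, fit) == pytest.approx((num / den) ** 2, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# dynamic fit
# ---------------------------------------------------------------------------

def _simulate_dhr(T, rng, rw_sd=(0.008, 0.005), amp=(0.1, 0.04), obs_sd=0.02, beta=-0.04):
    t = np.arange(1, T + 1)
    d = 9.5 - 6.5 * np.cos(OMEGA * t) + rng.normal(0, 1.0, T)
    y = -2.0 + beta * d
    for p, (q, a0) in enumerate(zip(rw_sd, amp), start=1):
        A = a0 + np.cumsum(rng.normal(0, q, T))
        B = a0 / 2 + np.cumsum(rng.normal(0, q, T))
        y = y + A * np.cos(p * OMEGA * t) + B * np.sin(p * OMEGA * t)
    return d, y + rng.normal(0, obs_sd, T)


class TestDynamicFit:
    def test_deterministic_given_data(self, rng):
        d, y = _simulate_dhr(55, rng)
        m1 = DynamicHarmonicRegression(k=2).fit(d, y)
        m2 = DynamicHarmonicRegression(k=2).fit(d, y)
        assert m1.loglik_ == m2.loglik_
        np.testing.assert_array_equal(m1.fitted_values_, m2.fitted_values_)

    def test_parameter_recovery(self):
        """Moderate-length series: hyperparameter estimates land within an
        order of magnitude of truth, observation variance within a factor 2
        (median over replicates)."""
        errs_h, errs_q = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            d, y = _simulate_dhr(160, rng)
            m = DynamicHarmonicRegression(k=2, n_starts=3).fit(d, y)
            errs_h.append(abs(np.log(m.obs_variance_ / 0.02**2)))
            errs_q.append(abs(np.log(max(m.rw_variance_[0], 1e-12) / 0.008**2)))
        assert np.median(errs_h) < np.log(2.0)
        assert np.median(errs_q) < np.log(10.0)

    def test_zero_rw_variance_shrinks_to_boundary(self):
        """Data from the static model drives the RW variance estimate toward
        zero (well below the observation variance)."""
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            d, y = _simulate_dhr(80, rng, rw_sd=(0.0, 0.0), amp=(0.1, 0.04), obs_sd=0.05)
            m = DynamicHarmonicRegression(k=2, n_starts=3).fit(d, y)
            hits += np.all(m.rw_variance_ < 0.01 * m.obs_variance_)
        assert hits >= int(0.9 * n_rep)

    def test_dynamic_loglik_at_least_static(self, rng):
        """The static model lies in the closure of the dynamic family, so the
        maximized dynamic log-likelihood can never fall below it."""
        for _ in range(3):
            d, y = _simulate_dhr(55, rng)
            m = DynamicHarmonicRegression(k=2).fit(d, y)
            ll_static = m.loglik_at(y, temperature=d, rw_variance=0.0)
            assert m.loglik_ >= ll_static - 1e-6


class TestSelectLag:
    def test_tie_breaks_toward_shorter_lag(self, rng):
        """A constant temperature-independent response makes every lag fit
        identically; the shorter lag must win."""
        daily = pd.Series(
            5.0, index=pd.date_range("2001-11-01", "2004-12-31", freq="D")
        )
        T = 30
        t = np.arange(1, T + 1)
        y = 0.3 * np.cos(OMEGA * t) + 0.1 * np.sin(OMEGA * t) + rng.normal(0, 0.05, T)
        # constant temperature is collinear: exclude it from the model so all
        # lags give the *same* series and identical fits
        table, best, fits = select_lag(
            y, daily, lags=(7, 0), k=1, anchor=ANCHOR, n_months=T,
            dynamic_kwargs={"include_temperature": False, "n_starts": 2},
        )
        assert table["r2_dynamic"].nunique() == 1
        assert best == 0

    def test_per_lag_failures_reported_not_fatal(self, rng):
        daily = gen_temperature(20, seed=1, anchor=ANCHOR, lead_days=0)
        T = 20
        y = rng.normal(0, 1, T) + np.sin(OMEGA * np.arange(1, T + 1))
        with pytest.warns(UserWarning):
            table, best, fits = select_lag(
                y, daily, lags=(0, "1m"), k=1, anchor=ANCHOR, n_months=T,
                dynamic_kwargs={"n_starts": 2},
            )
        assert table.shape[0] == 2
        assert np.isfinite(table.set_index("lag").loc["0d", "r2_dynamic"])


class TestAnomalyIdentity:
    def test_identity_on_generic_instance(self, rng):
        T = 55
        t = np.arange(1, T + 1)
        d = 9.5 - 6.5 * np.cos(OMEGA * t + 0.3) + rng.normal(0, 1.5, T)
        y = -2 - 0.04 * d + 0.2 * np.cos(OMEGA * t) + rng.normal(0, 0.05, T)
        *_, max_diff = temperature_anomaly_identity(y, d, k=1)
        assert max_diff < 1e-8

    def test_orthogonal_temperature_keeps_coefficients(self, rng):
        """If the temperature is already orthogonal to the harmonics the
        anomaly transform changes nothing at all."""
        T = 48
        t = np.arange(1, T + 1)
        harm = np.column_stack([np.cos(OMEGA * t), np.sin(OMEGA * t)])
        d_raw = rng.normal(0, 2, T)
        d = d_raw - harm @ np.linalg.lstsq(harm, d_raw, rcond=None)[0]
        y = 1 + 0.3 * d + 0.5 * np.cos(OMEGA * t) + rng.normal(0, 0.1, T)
        coef_raw, coef_star, *_, max_diff = temperature_anomaly_identity(y, d, k=1)
        np.testing.assert_allclose(coef_raw, coef_star, atol=1e-8)
        assert max_diff < 1e-10

    def test_constant_temperature_degenerate_but_identical(self, rng):
        T = 36
        t = np.arange(1, T + 1)
        d = np.full(T, 9.0)
        y = 0.2 * np.cos(OMEGA * t) + rng.normal(0, 0.1, T)
        *_, max_diff = temperature_anomaly_identity(y, d, k=1)
        assert max_diff < 1e-8
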