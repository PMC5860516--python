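"""Stage 1: area-wide seasonal models.

``DynamicHarmonicRegression`` fits the random-walk-coefficient harmonic
regression by maximum likelihood (Kalman prediction-error decomposition,
concentrated over the observation variance, quasi-Newton with deterministic
multi-starts on the log variance-ratio scale).  ``StaticHarmonicRegression``
is the time-invariant OLS counterpart.  ``select_lag`` fits one dynamic model
per candidate temperature lag and ranks them by R^2 (squared Pearson
correlation between observed and fitted values); ties break toward the
shorter lag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from . import kalman
from .kalman import OMEGA, build_state_space, harmonic_design, kalman_filter, kalman_smooth
from .temperature import DEFAULT_LAGS, lag_days, lag_label, lag_temperature

__all__ = [
    "DynamicHarmonicRegression",
    "StaticHarmonicRegression",
    "goodness_of_fit",
    "select_lag",
    "temperature_anomaly_identity",
    "lag_temperature",
]


def goodness_of_fit(observed, fitted) -> float:
    """R^2 as the squared Pearson correlation between observed and fitted.

    Computed over months where both are non-missing; requires at least three
    pairs and nonzero variance on both sides.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have the same length")
    ok = np.isfinite(obs) & np.isfinite(fit)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing (observed, fitted) pairs")
    o, f = obs[ok], fit[ok]
    so, sf = o.std(), f.std()
    if so == 0 or sf == 0:
        raise ValueError("R^2 undefined: zero variance in observed or fitted values")
    r = float(np.corrcoef(o, f)[0, 1])
    return r * r


def _as_temperature_column(X):
    """Accept None, a 1-D series or a (T, 1) column for the temperature."""
    if X is None:
        return None
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2:
        if arr.shape[1] == 0:
            return None
        if arr.shape[1] != 1:
            raise ValueError("expected a single temperature column")
        arr = arr[:, 0]
    return arr


class StaticHarmonicRegression(RegressorMixin, BaseEstimator):
    """Harmonic regression with time-invariant coefficients, fitted by OLS.

    Parameters
    ----------
    k : int
        Number of harmonics (pairs of cos/sin terms at multiples of the
        annual frequency 2*pi/12).  ``k=0`` with no temperature reduces to an
        intercept-only fit.
    include_temperature : bool
        Whether a monthly temperature column is part of the design.
    """

    def __init__(self, k: int = 2, include_temperature: bool = True, omega: float = OMEGA):
        self.k = k
        self.include_temperature = include_temperature
        self.omega = omega

    def _design(self, temperature, month_index):
        T = len(month_index)
        cols = [np.ones(T)]
        names = ["intercept"]
        if self.include_temperature:
            if temperature is None:
                raise ValueError("include_temperature=True but no temperature given")
            cols.append(np.asarray(temperature, dtype=float))
            names.append("temperature")
        if self.k:
            cols.append(harmonic_design(month_index, self.k, self.omega))
            for p in range(1, self.k + 1):
                names += [f"A{p}", f"B{p}"]
        return np.column_stack(cols), names

    def fit(self, X, y):
        temp = _as_temperature_column(X)
        y = np.asarray(y, dtype=float)
        month_index = np.arange(1, len(y) + 1)
        D, names = self._design(temp, month_index)
        ok = np.isfinite(y) & np.all(np.isfinite(D), axis=1)
        if ok.sum() < D.shape[1]:
            raise ValueError("fewer usable months than regression coefficients")
        rank = np.linalg.matrix_rank(D[ok])
        if rank < D.shape[1]:
            # name the offending columns via the QR diagonal
            _, R = np.linalg.qr(D[ok])
            diag = np.abs(np.diag(R))
            bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        coef, *_ = np.linalg.lstsq(D[ok], y[ok], rcond=None)
        self.coef_ = pd.Series(coef, index=names)
        fitted = np.full(len(y), np.nan)
        rows = np.all(np.isfinite(D), axis=1)
        fitted[rows] = D[rows] @ coef
        self.fitted_values_ = fitted
        self.resid_ = y - fitted
        self.r2_ = goodness_of_fit(y, fitted)
        self.month_index_ = month_index
        return self

    def predict(self, X):
        temp = _as_temperature_column(X)
        T = len(temp) if temp is not None else len(self.month_index_)
        D, _ = self._design(temp, np.arange(1, T + 1))
        return D @ self.coef_.to_numpy()


class DynamicHarmonicRegression(RegressorMixin, BaseEstimator):
    """Dynamic harmonic regression fitted by maximum likelihood.

    The harmonic coefficients follow random walks (one innovation variance
    shared within each cos/sin pair, distinct across harmonics unless
    ``shared_rw_variance=True``); intercept and temperature slope are constant
    states.  Hyperparameters are estimated by maximizing the concentrated
    Kalman prediction-error log-likelihood over the log variance ratios, with
    deterministic multi-starts.

    Attributes (after ``fit``)
    --------------------------
    rw_variance_ : ndarray of shape (k,)
        Estimated random-walk innovation variances.
    obs_variance_ : float
        Estimated observation variance sigma_u^2.
    loglik_ : float
        Maximized (burn-in-excluded) log-likelihood.
    smoothed_states_ : pandas.DataFrame, T x state-dim
    fitted_values_ : ndarray
        Smoothed fitted values mu_hat(t).
    r2_ : float
    converged_ : bool
    """

    #: deterministic multi-start points on the log10 variance-ratio scale
    _STARTS = (-8.0, -5.0, -3.0, -1.5, 0.0)

    def __init__(
        self,
        k: int = 2,
        include_temperature: bool = True,
        shared_rw_variance: bool = False,
        trend: bool = False,
        n_starts: int = 5,
        diffuse_scale: float = 1e7,
        omega: float = OMEGA,
    ):
        self.k = k
        self.include_temperature = include_temperature
        self.shared_rw_variance = shared_rw_variance
        self.trend = trend
        self.n_starts = n_starts
        self.diffuse_scale = diffuse_scale
        self.omega = omega

    # -- internal -----------------------------------------------------------
    def _build(self, temp, T, rw_ratio, vary):
        return build_state_space(
            self.k,
            temperature=temp if self.include_temperature else None,
            rw_variance=np.asarray(rw_ratio) * vary,
            obs_variance=vary,
            n_months=T,
            diffuse_var=self.diffuse_scale * vary,
            omega=self.omega,
            trend=self.trend,
        )

    @staticmethod
    def _concentrated(f):
        """Profile the common variance scale out of the filter output."""
        obs = f["observed"]
        keep = np.where(obs)[0][f["n_burnin"]:]
        n = len(keep)
        if n == 0:
            raise ValueError("no post-burn-in observations")
        v, F = f["innovations"][keep], f["innovation_var"][keep]
        s2 = float(np.mean(v * v / F))
        ll = -0.5 * n * (np.log(2 * np.pi) + 1 + np.log(s2)) - 0.5 * np.sum(np.log(F))
        return ll, s2

    def fit(self, X, y):
        temp = _as_temperature_column(X)
        y = np.asarray(y, dtype=float)
        T = len(y)
        ok = np.isfinite(y)
        if temp is not None:
            ok &= np.isfinite(temp)
        n_par = 1 if self.shared_rw_variance else self.k
        dim = 1 + int(self.include_temperature) + int(self.trend) + 2 * self.k
        if ok.sum() < dim + 2:
            raise ValueError("too few non-missing months to fit the dynamic model")
        vary = float(np.var(y[np.isfinite(y)]))
        if vary == 0:
            raise ValueError("response has zero variance")

        def negll(theta):
            ratio = np.exp(theta)
            if not self.shared_rw_variance:
                rw = ratio
            else:
                rw = np.full(self.k, ratio[0])
            ss = self._build(temp, T, rw, vary)
            f = kalman_filter(ss, y)
            ll, _ = self._concentrated(f)
            return -ll

        LOG10 = np.log(10.0)
        bounds = [(-23.0, 6.0)] * n_par  # natural-log bounds on the variance ratio
        best = None
        results = []
        for s in self._STARTS[: self.n_starts]:
            x0 = np.full(n_par, s * LOG10)
            res = optimize.minimize(
                negll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 200},
            )
            results.append(res)
            if best is None or res.fun < best.fun - 0.0:
                best = res

        ratio = np.exp(best.x)
        rw_ratio = np.full(self.k, ratio[0]) if self.shared_rw_variance else ratio
        ss = self._build(temp, T, rw_ratio, vary)
        f = kalman_smooth(ss, y)
        ll, s2 = self._concentrated(f)

        # rescale to the concentrated optimum of the variance scale
        self.obs_variance_ = s2 * vary
        self.rw_variance_ = rw_ratio * s2 * vary
        self.loglik_ = float(ll)
        self.converged_ = bool(any(r.success for r in results))
        self.state_names_ = ss.state_names
        self.smoothed_states_ = pd.DataFrame(
            f["smoothed_mean"], columns=ss.state_names, index=np.arange(1, T + 1)
        )
        self.filtered_states_ = pd.DataFrame(
            f["filtered_mean"], columns=ss.state_names, index=np.arange(1, T + 1)
        )
        self.fitted_values_ = f["fitted"]
        self.innovations_ = f["innovations"]
        self.innovation_var_ = f["innovation_var"]
        self.resid_ = y - f["fitted"]
        self.r2_ = goodness_of_fit(y, f["fitted"])
        self.n_obs_ = f["n_obs"]
        return self

    def predict(self, X=None):
        """In-sample smoothed fitted values (the DHR is a smoother, not a
        forecaster in this package)."""
        return self.fitted_values_

    def loglik_at(self, y, temperature=None, rw_variance=0.0, obs_variance=None):
        """Burn-in-excluded log-likelihood at user-supplied variances.

        With ``rw_variance=0`` this evaluates the static-regression member of
        the dynamic family; ``obs_variance=None`` profiles it out.
        """
        y = np.asarray(y, dtype=float)
        temp = _as_temperature_column(temperature)
        vary = float(np.var(y[np.isfinite(y)]))
        if obs_variance is None:
            ss = self._build(temp, len(y), np.broadcast_to(rw_variance, (self.k,)) / vary, vary)
            f = kalman_filter(ss, y)
            ll, _ = self._concentrated(f)
            return float(ll)
        ss = build_state_space(
            self.k,
            temperature=temp if self.include_temperature else None,
            rw_variance=rw_variance,
            obs_variance=obs_variance,
            n_months=len(y),
            diffuse_var=self.diffuse_scale * vary,
            omega=self.omega,
            trend=self.trend,
        )
        f = kalman_filter(ss, y)
        keep = np.where(f["observed"])[0][f["n_burnin"]:]
        v, F = f["innovations"][keep], f["innovation_var"][keep]
        return float(-0.5 * np.sum(np.log(2 * np.pi) + np.log(F) + v * v / F))


def select_lag(
    y,
    daily_temp: pd.Series,
    lags=DEFAULT_LAGS,
    k: int = 2,
    anchor=None,
    n_months: int | None = None,
    dynamic_kwargs: dict | None = None,
):
    """Fit one DHR (and one static model) per candidate temperature lag.

    Returns
    -------
    table : pandas.DataFrame
        One row per lag: ``lag``, ``lag_days``, ``r2_dynamic``, ``r2_static``,
        ``loglik``, ``converged``, ``error``.  Per-lag failures are recorded,
        not fatal.
    best_lag :
        The lag whose dynamic fit has the highest R^2; exact ties break
        toward the shorter lag.
    fits : dict
        lag -> fitted DynamicHarmonicRegression (only for lags that fit).
    """
    y = np.asarray(y, dtype=float)
    if n_months is None:
        n_months = len(y)
    dynamic_kwargs = dict(dynamic_kwargs or {})
    dynamic_kwargs.setdefault("k", k)

    ordered = sorted(lags, key=lag_days)
    rows = []
    fits = {}
    for lag in ordered:
        row = {
            "lag": lag_label(lag),
            "lag_days": lag_days(lag),
            "r2_dynamic": np.nan,
            "r2_static": np.nan,
            "loglik": np.nan,
            "converged": False,
            "error": "",
        }
        try:
            d = lag_temperature(daily_temp, lag, anchor=anchor, n_months=n_months)
            dyn = DynamicHarmonicRegression(**dynamic_kwargs).fit(d.to_numpy(), y)
            fits[lag] = dyn
            row.update(
                r2_dynamic=dyn.r2_, loglik=dyn.loglik_, converged=dyn.converged_
            )
            stat = StaticHarmonicRegression(k=dynamic_kwargs["k"]).fit(d.to_numpy(), y)
            row["r2_static"] = stat.r2_
        except (ValueError, np.linalg.LinAlgError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)

    valid = table["r2_dynamic"].notna()
    if not valid.any():
        raise ValueError("no candidate lag could be fitted")
    best_pos = int(np.argmax(table.loc[valid, "r2_dynamic"].to_numpy()))
    best_lag = [ordered[i] for i in np.where(valid)[0]][best_pos]
    return table, best_lag, fits


def temperature_anomaly_identity(y, temperature, k: int = 1, omega: float = OMEGA):
    """Static fits with raw temperature vs. its seasonal-anomaly series.

    The anomaly series is the residual of regressing d(t) on the harmonic
    terms cos(w t), sin(w t) (no intercept).  Both parameterizations span the
    same column space, so the fitted seasonal curves are identical; the
    maximum absolute difference is returned as a numerical check.

    Returns ``(coef_raw, coef_anomaly, fitted_raw, fitted_anomaly, max_diff)``.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(temperature, dtype=float)
    t = np.arange(1, len(y) + 1)
    harm = harmonic_design(t, k, omega)
    # seasonal component of temperature (regression on harmonics only)
    g, *_ = np.linalg.lstsq(harm, d, rcond=None)
    d_star = d - harm @ g

    def _fit(dd):
        D = np.column_stack([np.ones(len(y)), dd, harm])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        return coef, D @ coef

    coef_raw, mu = _fit(d)
    coef_star, mu_star = _fit(d_star)
    max_diff = float(np.max(np.abs(mu_star - mu)))
    return coef_raw, coef_star, mu, mu_star, max_diff
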