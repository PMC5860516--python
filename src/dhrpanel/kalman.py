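"""Gaussian state-space machinery for the dynamic harmonic regression.

The DHR casts a seasonal regression

    Y(t) = a + beta d(t) + sum_p [A_{p,t} cos(p w t) + B_{p,t} sin(p w t)] + U_t

as a linear Gaussian state-space model: the state vector collects
(a, beta, A_1, B_1, ..., A_k, B_k), the transition is the identity (a and beta
are constants with zero innovation variance; each harmonic-coefficient pair
follows a random walk with a shared innovation variance), and the observation
vector at month t is (1, d(t), cos(p w t), sin(p w t), ...).

Diffuse initialization is approximated by a large finite prior variance
(``diffuse_scale`` times the sample variance of y), and the likelihood
contributions of the first state-dimension innovations are excluded from the
maximum-likelihood criterion so that the approximation does not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OMEGA = 2.0 * np.pi / 12.0


@dataclass
class StateSpace:
    """Time-invariant-transition state-space model with identity dynamics.

    Attributes
    ----------
    Z : (T, d) ndarray
        Observation vectors; rows with NaN mark months whose regressor is
        missing (the observation is then treated as missing).
    Q : (d,) ndarray
        Diagonal state-innovation variances (zeros for constant states).
    H : float
        Observation variance sigma_u^2.
    P0 : (d,) ndarray
        Diagonal of the (large, finite) diffuse prior variance of the state.
    state_names : tuple of str
    """

    Z: np.ndarray
    Q: np.ndarray
    H: float
    P0: np.ndarray
    state_names: tuple = ()

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("Z must be 2-D (T x d)")
        d = self.Z.shape[1]
        if self.Q.shape != (d,) or self.P0.shape != (d,):
            raise ValueError("Q and P0 must have length equal to the state dimension")
        if np.any(self.Q < 0) or self.H < 0 or np.any(self.P0 <= 0):
            raise ValueError("variances must be nonnegative (P0 strictly positive)")

    @property
    def dim(self) -> int:
        return self.Z.shape[1]


def harmonic_design(month_index: np.ndarray, k: int, omega: float = OMEGA) -> np.ndarray:
    """Columns cos(p w t), sin(p w t) for p = 1..k."""
    t = np.asarray(month_index, dtype=float)
    cols = []
    for p in range(1, k + 1):
        cols.append(np.cos(p * omega * t))
        cols.append(np.sin(p * omega * t))
    return np.column_stack(cols) if cols else np.empty((len(t), 0))


def build_state_space(
    k: int,
    temperature=None,
    rw_variance=0.0,
    obs_variance: float = 1.0,
    month_index=None,
    diffuse_var: float = 1e7,
    omega: float = OMEGA,
    trend: bool = False,
    n_months: int | None = None,
) -> StateSpace:
    """Assemble the DHR state-space model.

    State ordering: intercept a, [temperature slope beta], [trend slope],
    then (A_p, B_p) for p = 1..k.  ``rw_variance`` is either a scalar shared
    by every harmonic pair or a length-k vector (one variance per pair).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k * omega > np.pi - 1e-9:
        raise ValueError("k harmonics exceed the Nyquist frequency for monthly data")
    if month_index is None:
        if n_months is None:
            if temperature is None:
                raise ValueError("need month_index, n_months or temperature")
            n_months = len(temperature)
        month_index = np.arange(1, n_months + 1)
    month_index = np.asarray(month_index)
    T = len(month_index)

    rw = np.broadcast_to(np.asarray(rw_variance, dtype=float), (k,))
    if np.any(rw < 0) or obs_variance < 0:
        raise ValueError("variances must be nonnegative")

    cols = [np.ones(T)]
    names = ["intercept"]
    q = [0.0]
    if temperature is not None:
        cols.append(np.asarray(temperature, dtype=float))
        names.append("temperature")
        q.append(0.0)
    if trend:
        cols.append((month_index - month_index.mean()) / 12.0)
        names.append("trend")
        q.append(0.0)
    harm = harmonic_design(month_index, k, omega)
    cols.append(harm)
    for p in range(1, k + 1):
        names += [f"A{p}", f"B{p}"]
        q += [rw[p - 1], rw[p - 1]]
    Z = np.column_stack(cols)
    Q = np.asarray(q)
    P0 = np.full(Z.shape[1], float(diffuse_var))
    return StateSpace(Z, Q, float(obs_variance), P0, tuple(names))


def kalman_filter(ss: StateSpace, y: np.ndarray) -> dict:
    """Kalman filter with prediction-error-decomposition log-likelihood.

    Missing observations (NaN in ``y`` or in the corresponding row of ``Z``)
    skip the measurement update.  The reported ``loglik`` excludes the burn-in
    contributions of the first ``d`` (state dimension) observed innovations;
    ``loglik_full`` keeps them.
    """
    y = np.asarray(y, dtype=float)
    Z, Qd, H = ss.Z, ss.Q, ss.H
    T, d = Z.shape
    if len(y) != T:
        raise ValueError("y and state space cover different numbers of months")
    obs = np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    if not obs.any():
        raise ValueError("series has no usable (non-missing) observations")

    a = np.zeros(d)
    P = np.diag(ss.P0).copy()
    Q = np.diag(Qd)
    I = np.eye(d)

    att = np.empty((T, d))
    Ptt = np.empty((T, d, d))
    apred = np.empty((T, d))
    Ppred = np.empty((T, d, d))
    v = np.full(T, np.nan)
    F = np.full(T, np.nan)
    ll_terms = np.zeros(T)

    n_seen = 0
    LOG2PI = np.log(2.0 * np.pi)
    for t in range(T):
        apred[t] = a
        Ppred[t] = P
        if obs[t]:
            z = Z[t]
            Pz = P @ z
            Ft = float(z @ Pz + H)
            vt = float(y[t] - z @ a)
            K = Pz / Ft
            a = a + K * vt
            IKz = I - np.outer(K, z)
            P = IKz @ P @ IKz.T + H * np.outer(K, K)  # Joseph form
            P = 0.5 * (P + P.T)
            v[t] = vt
            F[t] = Ft
            ll_terms[t] = -0.5 * (LOG2PI + np.log(Ft) + vt * vt / Ft)
            n_seen += 1
        att[t] = a
        Ptt[t] = P
        P = P + Q

    order = np.cumsum(obs)  # 1-based rank of each observed month
    burn = obs & (order <= d)
    loglik_full = float(ll_terms[obs].sum())
    loglik = float(ll_terms[obs & ~burn].sum())
    return {
        "loglik": loglik,
        "loglik_full": loglik_full,
        "filtered_mean": att,
        "filtered_cov": Ptt,
        "predicted_mean": apred,
        "predicted_cov": Ppred,
        "innovations": v,
        "innovation_var": F,
        "observed": obs,
        "n_burnin": int(min(d, obs.sum())),
        "n_obs": int(obs.sum()),
    }


def kalman_smooth(ss: StateSpace, y: np.ndarray) -> dict:
    """Fixed-interval (RTS) smoother on top of :func:`kalman_filter`.

    Returns smoothed state means/covariances and the smoothed fitted values
    mu_hat(t) = Z_t . smoothed state at t (NaN where Z has missing entries).
    """
    f = kalman_filter(ss, y)
    Z, Qd = ss.Z, ss.Q
    T, d = Z.shape
    Q = np.diag(Qd)

    alpha = f["filtered_mean"].copy()
    V = f["filtered_cov"].copy()
    for t in range(T - 2, -1, -1):
        Pnext = f["filtered_cov"][t] + Q  # one-step prediction cov for t+1
        C = np.linalg.solve(Pnext.T, f["filtered_cov"][t].T).T
        alpha[t] = f["filtered_mean"][t] + C @ (alpha[t + 1] - f["filtered_mean"][t])
        V[t] = f["filtered_cov"][t] + C @ (V[t + 1] - Pnext) @ C.T
        V[t] = 0.5 * (V[t] + V[t].T)

    zrows = np.all(np.isfinite(Z), axis=1)
    fitted = np.full(T, np.nan)
    fitted[zrows] = np.einsum("td,td->t", Z[zrows], alpha[zrows])
    out = dict(f)
    out.update(
        smoothed_mean=alpha,
        smoothed_cov=V,
        fitted=fitted,
    )
    return out
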