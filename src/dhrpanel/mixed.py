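"""Stage 2: random-intercept linear mixed model with an offset.

The practice-month log rate is modelled as

    y_jt = offset_t + x_jt' a + b_j + eps_jt,
    b_j ~ N(0, sigma_b^2),  eps_jt ~ N(0, sigma_e^2),

with the stage-1 fitted area-wide curve entering as the offset (implicit
coefficient exactly 1).  Estimation profiles the (RE)ML criterion down to a
one-dimensional optimization over lambda = sigma_b^2 / sigma_e^2 on the log
scale; fixed effects are then closed-form GLS.  Wald standard errors use the
GLS covariance; t and two-sided p values use residual degrees of freedom
N - p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .diagnostics import acf

LOG2PI = np.log(2.0 * np.pi)


class RandomInterceptModel(BaseEstimator):
    """Linear mixed model with a single random intercept per group.

    Parameters
    ----------
    method : {"reml", "ml"}
        Estimation criterion.  REML (default) gives unbiased variance
        components; ML is available for likelihood comparisons.
    fit_intercept : bool
        Prepend an intercept column to the fixed-effects design.

    Attributes (after ``fit``)
    --------------------------
    fe_params_ : pandas.Series         GLS fixed-effect estimates.
    fe_se_ : pandas.Series             Wald standard errors.
    tvalues_, pvalues_ : pandas.Series t statistics and two-sided p values
                                       (residual df N - p).
    sigma_b2_, sigma_e2_ : float       variance components.
    lambda_ : float                    sigma_b^2 / sigma_e^2.
    blups_ : pandas.DataFrame          per-group conditional means and
                                       conditional variances.
    resid_ : ndarray                   y - offset - X a - b_hat.
    loglik_ : float                    ML log-likelihood at the fitted
                                       parameters (dense-Gaussian value).
    criterion_ : float                 maximized (RE)ML criterion.
    boundary_ : bool                   True if lambda was estimated at the
                                       boundary (sigma_b^2 = 0 or the upper
                                       search bound).
    """

    def __init__(self, method: str = "reml", fit_intercept: bool = True):
        self.method = method
        self.fit_intercept = fit_intercept

    # -- profiled criterion -------------------------------------------------
    @staticmethod
    def _group_stats(X, r, groups):
        """Per-group cross products needed by the compound-symmetry algebra."""
        codes, uniques = pd.factorize(groups, sort=True)
        n_groups = len(uniques)
        p = X.shape[1]
        XtX = X.T @ X
        Xtr = X.T @ r
        rtr = float(r @ r)
        # group sums
        Sx = np.zeros((n_groups, p))
        Sr = np.zeros(n_groups)
        nj = np.bincount(codes, minlength=n_groups).astype(float)
        np.add.at(Sx, codes, X)
        np.add.at(Sr, codes, r)
        return codes, uniques, nj, XtX, Xtr, rtr, Sx, Sr

    @staticmethod
    def _profiled(lam, nj, XtX, Xtr, rtr, Sx, Sr):
        """GLS pieces for Sigma = I + lam * Z Z' (unit residual variance)."""
        w = lam / (1.0 + nj * lam)          # per-group Sherman-Morrison weight
        A = XtX - (Sx * w[:, None]).T @ Sx  # X' Sigma^-1 X
        bvec = Xtr - Sx.T @ (w * Sr)        # X' Sigma^-1 r
        c = rtr - float(Sr @ (w * Sr))      # r' Sigma^-1 r
        beta = np.linalg.solve(A, bvec)
        Q = c - float(beta @ bvec)          # residual GLS quadratic form
        logdet_sigma = float(np.sum(np.log1p(nj * lam)))
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("X' Sigma^-1 X not positive definite")
        return beta, A, Q, logdet_sigma, logdet_A

    def _criterion(self, lam, N, p, nj, XtX, Xtr, rtr, Sx, Sr):
        """-2 x profiled (RE)ML criterion at lambda (sigma_e^2 profiled out)."""
        _, _, Q, logdet_sigma, logdet_A = self._profiled(lam, nj, XtX, Xtr, rtr, Sx, Sr)
        if self.method == "ml":
            s2 = Q / N
            return N * (LOG2PI + np.log(s2)) + logdet_sigma + N
        s2 = Q / (N - p)
        return (N - p) * (LOG2PI + np.log(s2)) + logdet_sigma + logdet_A + (N - p)

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y, groups=None, offset=None):
        if groups is None:
            raise ValueError("groups is required (one label per record)")
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        y = np.asarray(y, dtype=float)
        N = len(y)
        offset = np.zeros(N) if offset is None else np.asarray(offset, dtype=float)
        if len(offset) != N:
            raise ValueError("offset must be defined for every record")
        r = y - offset

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
            names = [f"x{j}" for j in range(Xm.shape[1])]
        if self.fit_intercept:
            Xm = np.column_stack([np.ones(N), Xm])
            names = ["intercept"] + names
        p = Xm.shape[1]
        if not np.all(np.isfinite(Xm)) or not np.all(np.isfinite(r)):
            raise ValueError("design, response and offset must be finite")
        rank = np.linalg.matrix_rank(Xm)
        if rank < p:
            _, R = np.linalg.qr(Xm)
            diag = np.abs(np.diag(R))
            bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"rank-deficient fixed-effects design; columns: {bad}")

        codes, uniques, nj, XtX, Xtr, rtr, Sx, Sr = self._group_stats(Xm, r, groups)
        if len(uniques) < 2:
            raise ValueError("need at least 2 groups (practices)")

        crit = lambda u: self._criterion(np.exp(u), N, p, nj, XtX, Xtr, rtr, Sx, Sr)
        LB, UB = -30.0, 30.0
        res = optimize.minimize_scalar(
            crit, bounds=(LB, UB), method="bounded", options={"xatol": 1e-11}
        )
        u_hat, f_hat = res.x, res.fun
        # candidate: exact boundary lambda = 0
        f0 = self._criterion(0.0, N, p, nj, XtX, Xtr, rtr, Sx, Sr)
        boundary = False
        if f0 <= f_hat:
            lam = 0.0
            f_hat = f0
            boundary = True
        else:
            lam = float(np.exp(u_hat))
            boundary = u_hat < LB + 1e-6 or u_hat > UB - 1e-6

        beta, A, Q, logdet_sigma, _ = self._profiled(lam, nj, XtX, Xtr, rtr, Sx, Sr)
        dof = N if self.method == "ml" else N - p
        s2 = Q / dof
        cov = s2 * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        df_resid = N - p
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

        self.feature_names_ = names
        self.fe_params_ = pd.Series(beta, index=names)
        self.fe_se_ = pd.Series(se, index=names)
        self.tvalues_ = pd.Series(tvals, index=names)
        self.pvalues_ = pd.Series(pvals, index=names)
        self.fe_cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.df_resid_ = df_resid
        self.sigma_e2_ = float(s2)
        self.sigma_b2_ = float(lam * s2)
        self.lambda_ = float(lam)
        self.boundary_ = bool(boundary)
        self.criterion_ = float(-0.5 * f_hat)

        # ML log-likelihood at the fitted parameters (for oracle comparisons)
        _, _, Qb, lds, _ = self._profiled(lam, nj, XtX, Xtr, rtr, Sx, Sr)
        self.loglik_ = float(
            -0.5 * (N * (LOG2PI + np.log(self.sigma_e2_)) + lds + Qb / self.sigma_e2_)
        )

        # BLUPs: shrunken group means of the fixed-effect residuals
        e_fixed = r - Xm @ beta
        sum_e = np.zeros(len(uniques))
        np.add.at(sum_e, codes, e_fixed)
        shrink = nj * lam / (1.0 + nj * lam)
        blup = np.where(nj > 0, shrink * sum_e / np.maximum(nj, 1), 0.0)
        cond_var = self.sigma_b2_ / (1.0 + nj * lam)
        self.blups_ = pd.DataFrame(
            {
                "blup": blup,
                "cond_var": cond_var,
                "n_obs": nj.astype(int),
                "raw_mean_resid": np.where(nj > 0, sum_e / np.maximum(nj, 1), np.nan),
            },
            index=pd.Index(uniques, name="practice_id"),
        )

        self.groups_ = np.asarray(groups)
        self.group_codes_ = codes
        self.offset_ = offset
        self.resid_ = e_fixed - blup[codes]
        self.fitted_values_ = y - self.resid_
        self.n_obs_ = N
        return self

    def predict(self, X, groups=None, offset=None):
        """Conditional predictions offset + X a + b_hat (b_hat = 0 for unseen
        groups)."""
        if isinstance(X, pd.DataFrame):
            Xm = X[self.feature_names_[1:] if self.fit_intercept else self.feature_names_].to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
        if self.fit_intercept:
            Xm = np.column_stack([np.ones(len(Xm)), Xm])
        out = Xm @ self.fe_params_.to_numpy()
        if offset is not None:
            out = out + np.asarray(offset, dtype=float)
        if groups is not None:
            bl = self.blups_["blup"]
            out = out + np.asarray([bl.get(g, 0.0) for g in groups])
        return out


def blup_intervals(model: RandomInterceptModel, level: float = 0.95) -> pd.DataFrame:
    """Central prediction intervals for the practice random effects.

    Returns one row per practice, sorted ascending by the conditional mean
    (BLUP), with ``lower``/``upper`` at the requested level based on the
    conditional variance.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not hasattr(model, "blups_"):
        raise ValueError("model is not fitted")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = model.blups_[["blup", "cond_var", "n_obs"]].copy()
    half = z * np.sqrt(out["cond_var"].to_numpy())
    out["lower"] = out["blup"] - half
    out["upper"] = out["blup"] + half
    return out.sort_values("blup", kind="mergesort")


def residual_checks(model: RandomInterceptModel, months=None, n_bins: int = 10, max_lag: int = 12) -> dict:
    """Descriptive residual diagnostics (no pass/fail verdicts).

    Returns a dict with

    - ``binned``: residual means/SDs/counts in ``n_bins`` bins of the fitted
      values (linearity / homoscedasticity check);
    - ``qq``: theoretical vs. sample standard-normal quantile pairs;
    - ``acf``: per-practice residual autocorrelations, lags 0..``max_lag``.
    """
    resid = model.resid_
    fitted = model.fitted_values_

    edges = np.quantile(fitted, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    idx = np.clip(np.digitize(fitted, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            rows.append(
                {
                    "bin_center": float(fitted[sel].mean()),
                    "mean_resid": float(resid[sel].mean()),
                    "sd_resid": float(resid[sel].std(ddof=1)) if sel.sum() > 1 else np.nan,
                    "count": int(sel.sum()),
                }
            )
    binned = pd.DataFrame(rows)

    n = len(resid)
    order = np.sort((resid - resid.mean()) / resid.std(ddof=0))
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo, "sample": order})

    acf_rows = {}
    groups = model.groups_
    for g in model.blups_.index:
        sel = groups == g
        r = resid[sel]
        if months is not None:
            m = np.asarray(months)[sel]
            r = r[np.argsort(m, kind="mergesort")]
        if len(r) > max_lag and np.std(r) > 0:
            acf_rows[g] = acf(r, max_lag)
    acf_df = pd.DataFrame(acf_rows).T
    acf_df.columns = [f"lag{h}" for h in range(acf_df.shape[1])]
    return {"binned": binned, "qq": qq, "acf": acf_df}
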