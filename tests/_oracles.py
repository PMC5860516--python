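"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's recursive algorithms: the state-space
quantities are computed from the dense joint Gaussian distribution of states
and observations (in extended precision, since the large diffuse prior
variance makes the dense covariance badly conditioned in float64), the
mixed-model likelihood from an explicitly assembled block covariance matrix,
and least squares from the normal equations.
"""

import numpy as np
from scipy.stats import multivariate_normal

LD = np.longdouble


def _chol_ld(A):
    """Cholesky factorization with explicit loops (LAPACK has no longdouble)."""
    n = A.shape[0]
    L = np.zeros_like(A)
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j] - L[i, :j] @ L[j, :j]
            L[i, j] = np.sqrt(s) if i == j else s / L[j, j]
    return L


def _forward_ld(L, b):
    x = np.zeros_like(b)
    for i in range(len(b)):
        x[i] = (b[i] - L[i, :i] @ x[:i]) / L[i, i]
    return x


def _backward_ld(L, b):
    n = len(b)
    x = np.zeros_like(b)
    for i in range(n - 1, -1, -1):
        x[i] = (b[i] - L[i + 1 :, i] @ x[i + 1 :]) / L[i, i]
    return x


def _mvn_logpdf_ld(x, S):
    L = _chol_ld(S)
    z = _forward_ld(L, x)
    return -LD(0.5) * len(x) * np.log(LD(2) * np.pi) - np.log(np.diag(L)).sum() - LD(0.5) * (z @ z)


def dense_dhr(Z, Q, H, P0, y):
    """Dense joint-Gaussian log-likelihood and smoothed state means.

    The state follows alpha_t = alpha_{t-1} + eta_t with alpha_1 ~ N(0, P0)
    (diagonal), eta ~ N(0, diag(Q)); y_t = Z_t alpha_t + u_t.  Returns the
    conditional log-likelihood excluding the first d observed months (the
    same burn-in convention as the filter) and E[alpha_t | all observed y].
    """
    Z = np.asarray(Z, LD)
    y = np.asarray(y, LD)
    Q = np.asarray(Q, LD)
    P0 = np.asarray(P0, LD)
    H = LD(H)
    T, d = Z.shape
    obs = np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    oidx = np.where(obs)[0]
    n = len(oidx)

    # Cov(alpha_t, alpha_s) = P0 + Q * (min(t, s) - 1), elementwise diagonal
    tgrid = np.arange(1, T + 1)
    mins = (np.minimum.outer(tgrid, tgrid) - 1).astype(LD)
    Sy = np.zeros((n, n), dtype=LD)
    for a, ta in enumerate(oidx):
        for b, tb in enumerate(oidx):
            Sy[a, b] = Z[ta] @ ((P0 + Q * mins[ta, tb]) * Z[tb])
    Sy[np.diag_indices(n)] += H

    yo = y[oidx]
    ll_full = _mvn_logpdf_ld(yo, Sy)
    burn = min(d, n)
    ll_head = _mvn_logpdf_ld(yo[:burn], Sy[:burn, :burn]) if burn > 0 else LD(0.0)
    loglik = float(ll_full - ll_head)

    # E[alpha_t | y] = Cov(alpha_t, y) Sy^-1 y
    L = _chol_ld(Sy)
    Sy_inv_y = _backward_ld(L, _forward_ld(L, yo))
    smoothed = np.zeros((T, d))
    for t in range(T):
        Cay = np.empty((d, n), dtype=LD)
        for b, tb in enumerate(oidx):
            Cay[:, b] = (P0 + Q * mins[t, tb]) * Z[tb]
        smoothed[t] = (Cay @ Sy_inv_y).astype(float)
    return loglik, smoothed


def dense_mixed_loglik(y, X, groups, beta, sigma_b2, sigma_e2, offset=None):
    """Gaussian log-density of a random-intercept model from the dense
    block compound-symmetry covariance."""
    y = np.asarray(y, float)
    N = len(y)
    if offset is not None:
        y = y - np.asarray(offset, float)
    V = sigma_e2 * np.eye(N)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        V[np.ix_(idx, idx)] += sigma_b2
    mu = np.asarray(X, float) @ np.asarray(beta, float)
    return float(multivariate_normal.logpdf(y, mean=mu, cov=V))


def normal_equations_ols(D, y):
    """Least squares via explicit normal equations."""
    D = np.asarray(D, float)
    y = np.asarray(y, float)
    return np.linalg.solve(D.T @ D, D.T @ y)


def anova_components_balanced(Y):
    """Variance components from a (J groups x n per group) response matrix."""
    Y = np.asarray(Y, float)
    J, n = Y.shape
    gm = Y.mean(axis=1)
    msw = float(((Y - gm[:, None]) ** 2).sum() / (J * (n - 1)))
    msb = float(n * ((gm - Y.mean()) ** 2).sum() / (J - 1))
    return msw, (msb - msw) / n
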