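"""Temporal, spatial and spatiotemporal correlation diagnostics.

Implements the residual-checking toolkit for the two-stage model: the sample
autocorrelation function, the semivariance cloud v_ij = (y_i - y_j)^2 / 2,
binned empirical variograms over planar distance, permutation envelopes after
OLS trend-surface detrending, and the distance x time-lag spatiotemporal
variogram.  All estimators are purely empirical; no parametric variogram model
is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

#: default 1-km distance bins up to the 20-km study window, in meters
DEFAULT_BIN_EDGES_M = tuple(np.arange(0.0, 21.0) * 1000.0)


def acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelations for lags 0..max_lag.

    Uses the common convention of a single overall mean and the lag-0
    autocovariance as denominator, so ``acf[0] == 1`` exactly.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if max_lag < 0 or len(x) <= max_lag:
        raise ValueError("need length > max_lag >= 0")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    xc = x - x.mean()
    c0 = float(xc @ xc)
    if c0 == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    full = np.correlate(xc, xc, mode="full")[len(x) - 1 : len(x) + max_lag]
    return full / c0


@dataclass
class SemivarianceCloud:
    """All unordered pairs: planar distance (m), optional absolute time
    difference (months) and semivariance v_ij = (y_i - y_j)^2 / 2."""

    distance: np.ndarray
    semivariance: np.ndarray
    time_diff: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.distance)


def semivariance_cloud(values, locations, times=None) -> SemivarianceCloud:
    y = np.asarray(values, dtype=float)
    xy = np.asarray(locations, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("locations must be an (n, 2) array of planar coordinates")
    if len(y) != len(xy):
        raise ValueError("values and locations have mismatched lengths")
    dist = pdist(xy)
    semi = 0.5 * pdist(y[:, None], metric="sqeuclidean")
    tdiff = None
    if times is not None:
        tt = np.asarray(times, dtype=float)
        if len(tt) != len(y):
            raise ValueError("times and values have mismatched lengths")
        tdiff = pdist(tt[:, None], metric="cityblock")
    return SemivarianceCloud(dist, semi, tdiff)


@dataclass
class VariogramEstimate:
    """Binned empirical variogram.  Bins are left-closed right-open; empty
    bins carry a NaN mean (never zero-filled)."""

    bin_edges: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    n_discarded: int = 0

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "bin_mid": self.bin_mid,
                "count": self.count,
                "semivariance": self.mean,
            }
        )


def _bin_pairs(dist, bin_edges):
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    idx = np.digitize(dist, edges) - 1  # left-closed right-open
    keep = (idx >= 0) & (dist < edges[-1])
    return edges, idx, keep


def binned_variogram(cloud: SemivarianceCloud, bin_edges=DEFAULT_BIN_EDGES_M) -> VariogramEstimate:
    edges, idx, keep = _bin_pairs(cloud.distance, bin_edges)
    nb = len(edges) - 1
    if not keep.any():
        raise ValueError("no pair falls within the requested distance range")
    counts = np.bincount(idx[keep], minlength=nb)
    sums = np.bincount(idx[keep], weights=cloud.semivariance[keep], minlength=nb)
    mean = np.divide(sums, counts, out=np.full(nb, np.nan), where=counts > 0)
    return VariogramEstimate(edges, mean, counts, int((~keep).sum()))


def trend_surface_residuals(values, locations) -> np.ndarray:
    """OLS residuals of value ~ 1 + easting + northing."""
    y = np.asarray(values, dtype=float)
    xy = np.asarray(locations, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 sites for a linear trend surface")
    D = np.column_stack([np.ones(len(y)), xy])
    if np.linalg.matrix_rank(D) < 3:
        raise ValueError("collinear site coordinates: trend surface not identifiable")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ coef


@dataclass
class EnvelopeResult:
    """Observed variogram with a pointwise permutation envelope.

    The envelope is the pointwise min/max over ``n_perm`` variograms computed
    after randomly permuting the detrended values over the locations.
    """

    observed: VariogramEstimate
    lower: np.ndarray
    upper: np.ndarray
    inside: np.ndarray
    n_perm: int
    seed: object
    perm_variograms: np.ndarray  # (n_perm, n_bins), kept for calibration work

    @property
    def all_inside(self) -> bool:
        ok = self.observed.count > 0
        return bool(np.all(self.inside[ok]))

    def to_frame(self) -> pd.DataFrame:
        df = self.observed.to_frame()
        df["lower"] = self.lower
        df["upper"] = self.upper
        df["inside"] = self.inside
        return df


def permutation_envelope(
    values,
    locations,
    n_perm: int = 99,
    seed=None,
    bin_edges=DEFAULT_BIN_EDGES_M,
    detrend: bool = True,
) -> EnvelopeResult:
    """Permutation envelope for the binned variogram of (detrended) values.

    The values are first replaced by the residuals of an OLS linear trend
    surface; the observed binned variogram is then compared against the
    pointwise extremes of ``n_perm`` variograms obtained by randomly
    permuting the residuals among the locations.
    """
    y = np.asarray(values, dtype=float)
    xy = np.asarray(locations, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 sites for a meaningful envelope")
    r = trend_surface_residuals(y, xy) if detrend else y.copy()

    n = len(r)
    iu, ju = np.triu_indices(n, k=1)
    dist = np.sqrt(((xy[iu] - xy[ju]) ** 2).sum(axis=1))
    edges, idx, keep = _bin_pairs(dist, bin_edges)
    nb = len(edges) - 1
    idx_k = idx[keep]
    iu_k, ju_k = iu[keep], ju[keep]
    counts = np.bincount(idx_k, minlength=nb)

    def vg(vals):
        semi = 0.5 * (vals[iu_k] - vals[ju_k]) ** 2
        sums = np.bincount(idx_k, weights=semi, minlength=nb)
        return np.divide(sums, counts, out=np.full(nb, np.nan), where=counts > 0)

    observed = vg(r)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, nb))
    for b in range(n_perm):
        perms[b] = vg(rng.permutation(r))

    lower = np.full(nb, np.nan)
    upper = np.full(nb, np.nan)
    occupied = counts > 0
    if n_perm and occupied.any():
        lower[occupied] = perms[:, occupied].min(axis=0)
        upper[occupied] = perms[:, occupied].max(axis=0)
    with np.errstate(invalid="ignore"):
        inside = (observed >= lower) & (observed <= upper)
    est = VariogramEstimate(edges, observed, counts, int((~keep).sum()))
    return EnvelopeResult(est, lower, upper, inside, n_perm, seed, perms)


@dataclass
class STVariogram:
    """Mean semivariance per (distance bin x time lag) cell with counts."""

    bin_edges: np.ndarray
    time_lags: np.ndarray
    mean: np.ndarray   # (n_bins, n_lags)
    count: np.ndarray  # (n_bins, n_lags)

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        nb, nl = self.mean.shape
        return pd.DataFrame(
            {
                "bin_mid": np.repeat(self.bin_mid, nl),
                "time_lag": np.tile(self.time_lags, nb),
                "count": self.count.ravel(),
                "semivariance": self.mean.ravel(),
            }
        )


def st_variogram(
    values,
    locations,
    months,
    practice_ids,
    bin_edges=DEFAULT_BIN_EDGES_M,
    time_lags=(0, 1, 2, 3),
) -> STVariogram:
    """Spatiotemporal empirical variogram on a practice-month panel.

    For time lag 0 only contemporaneous distinct-site pairs contribute; at
    positive lags same-site pairs contribute to the 0-distance bin.  The
    statistic is symmetric in pair ordering.
    """
    df = pd.DataFrame(
        {
            "pid": np.asarray(practice_ids),
            "month": np.asarray(months),
            "val": np.asarray(values, dtype=float),
        }
    )
    wide = df.pivot(index="pid", columns="month", values="val")
    V = wide.to_numpy()
    n, T = V.shape
    if isinstance(locations, pd.DataFrame):
        xy = locations.loc[wide.index, ["easting", "northing"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(locations, dtype=float)
        if xy.shape != (n, 2):
            raise ValueError(
                "locations must be an (n_practices, 2) array ordered as sorted "
                "practice ids, or a DataFrame indexed by practice_id"
            )
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))

    edges = np.asarray(bin_edges, dtype=float)
    nb = len(edges) - 1
    bin_idx = np.digitize(dist, edges) - 1
    valid_bin = (bin_idx >= 0) & (dist < edges[-1])
    bin_idx = np.where(valid_bin, bin_idx, -1)

    M = np.isfinite(V)
    V0 = np.where(M, V, 0.0)
    Vsq = V0 * V0
    Mf = M.astype(float)

    lags = np.asarray(time_lags, dtype=int)
    means = np.full((nb, len(lags)), np.nan)
    counts = np.zeros((nb, len(lags)), dtype=int)
    for li, h in enumerate(lags):
        if h >= T:
            continue
        A, Am, Asq = V0[:, : T - h], Mf[:, : T - h], Vsq[:, : T - h]
        B, Bm, Bsq = V0[:, h:], Mf[:, h:], Vsq[:, h:]
        S = 0.5 * (Asq @ Bm.T + Am @ Bsq.T - 2.0 * A @ B.T)
        np.maximum(S, 0.0, out=S)  # guard tiny negative round-off
        C = Am @ Bm.T
        if h == 0:
            sel = np.triu(np.ones((n, n), dtype=bool), k=1)
        else:
            sel = np.ones((n, n), dtype=bool)
        sel &= valid_bin
        flat_bins = bin_idx[sel]
        counts[:, li] = np.bincount(flat_bins, weights=C[sel], minlength=nb).astype(int)
        sums = np.bincount(flat_bins, weights=S[sel], minlength=nb)
        with np.errstate(invalid="ignore"):
            means[:, li] = np.where(counts[:, li] > 0, sums / np.maximum(counts[:, li], 1), np.nan)
    return STVariogram(edges, lags, means, counts)
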