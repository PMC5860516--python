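"""Synthetic practice-month panel generator.

Generates panels with the statistical structure the two-stage model assumes:
an area-wide seasonal path whose harmonic coefficients drift between years as
random walks, a shared (optionally lagged) temperature driver, practice-level
covariates, practice random intercepts, and residuals that are iid, spatially
correlated (exponential in distance) or separable spatiotemporal (exponential
in space x AR(1) in time).  The ground truth used to build each panel is always
returned alongside it so that recovery tests never re-derive truth from data.

Default sizes mirror the motivating study design: 63 practices observed over
55 consecutive months in a 20 x 20 km window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import PracticePanel
from .temperature import lag_temperature, month_starts

TWO_PI = 2.0 * np.pi
OMEGA = TWO_PI / 12.0  # angular frequency of the annual cycle, per month


@dataclass
class PanelGenConfig:
    """Configuration of the synthetic panel generator.

    All magnitudes are on the log-rate scale unless stated otherwise.
    """

    n_practices: int = 63
    n_months: int = 55
    spatial_extent_m: float = 20_000.0
    anchor: str = "2002-01-01"

    # area-wide seasonal model
    k: int = 2                               # number of harmonics
    intercept: float = -2.0
    temp_coef: float = -0.04                 # per degree C
    temp_lag_days: int = 0                   # lag the true temperature effect
    rw_sd: tuple = (0.008, 0.005)            # RW innovation SD per harmonic pair
    init_amplitude_sd: tuple = (0.06, 0.03)  # SD of A_{p,0}, B_{p,0}
    obs_sd: float = 0.02                     # area-wide monthly shock SD

    # practice level
    covariate_effects: dict = field(
        default_factory=lambda: {
            "time_elapsed": -0.0005,
            "income": 0.08,
            "employment": 0.05,
            "age": 0.01,
        }
    )
    rand_intercept_sd: float = 0.1
    resid_sd: float = 0.05
    residual_correlation: str = "iid"        # iid | spatial | spatiotemporal
    spatial_range_m: float = 5_000.0
    ar_coef: float = 0.6

    # daily temperature process
    temp_mean: float = 9.5
    temp_amplitude: float = 6.5
    temp_noise_sd: float = 3.0

    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_practices < 2:
            raise ValueError("n_practices must be >= 2")
        if self.n_months < 13:
            raise ValueError("n_months must be >= 13 (one full cycle plus a month)")
        if self.spatial_extent_m <= 0:
            raise ValueError("spatial_extent_m must be > 0")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in (-1, 1)")
        for name in ("obs_sd", "rand_intercept_sd", "resid_sd", "temp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.rw_sd = tuple(np.broadcast_to(self.rw_sd, (self.k,)).astype(float))
        self.init_amplitude_sd = tuple(
            np.broadcast_to(self.init_amplitude_sd, (self.k,)).astype(float)
        )
        if any(s < 0 for s in self.rw_sd) or any(s < 0 for s in self.init_amplitude_sd):
            raise ValueError("random-walk and initial-amplitude SDs must be >= 0")
        if self.residual_correlation not in ("iid", "spatial", "spatiotemporal"):
            raise ValueError(
                "residual_correlation must be one of iid|spatial|spatiotemporal"
            )


def gen_temperature(
    n_months: int,
    seed=None,
    anchor: str = "2002-01-01",
    mean: float = 9.5,
    amplitude: float = 6.5,
    noise_sd: float = 3.0,
    coldest_doy: int = 15,
    lead_days: int = 31,
) -> pd.Series:
    """Daily mean-temperature series: annual sinusoid plus independent noise.

    The sinusoid attains its minimum around day-of-year ``coldest_doy``
    (mid-January by default).  ``lead_days`` extra days are prepended before
    the anchor month so that lagged monthly averages remain computable.
    """
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    starts = month_starts(anchor, n_months)
    first = starts[0] - pd.Timedelta(days=int(lead_days))
    last = starts[-1] + pd.offsets.MonthBegin(1) - pd.Timedelta(days=1)
    days = pd.date_range(first, last, freq="D")
    doy = days.dayofyear.to_numpy()
    seasonal = mean - amplitude * np.cos(TWO_PI * (doy - coldest_doy) / 365.25)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(days))
    return pd.Series(seasonal + noise, index=days, name="temp_c")


def gen_locations(n: int, extent_m: float, seed=None) -> pd.DataFrame:
    """``n`` distinct practice locations uniform on the [0, extent]^2 window."""
    if n < 2:
        raise ValueError("need at least 2 locations")
    if extent_m <= 0:
        raise ValueError("extent_m must be > 0")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, extent_m, size=(n, 2))
    # continuous uniforms are a.s. distinct; guard against pathological seeds
    while len(np.unique(xy, axis=0)) < n:  # pragma: no cover
        xy = rng.uniform(0.0, extent_m, size=(n, 2))
    ids = [f"p{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(xy, columns=["easting", "northing"], index=pd.Index(ids, name="practice_id"))


def _smooth_spatial_field(locations: np.ndarray, extent: float, rng) -> np.ndarray:
    """Standardized smooth surface over the window: random low-frequency
    trigonometric components plus a small white-noise nugget."""
    n = locations.shape[0]
    f = np.zeros(n)
    for _ in range(3):
        freq = rng.uniform(0.5, 1.5, size=2) / extent
        phase = rng.uniform(0.0, TWO_PI)
        amp = rng.normal(0.0, 1.0)
        f += amp * np.sin(TWO_PI * locations @ freq + phase)
    f /= np.sqrt(3.0)
    f += rng.normal(0.0, 0.3, size=n)
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _residuals(cfg: PanelGenConfig, dist: np.ndarray, rng) -> np.ndarray:
    """(n_practices x n_months) residual field per the correlation switch."""
    n, T = cfg.n_practices, cfg.n_months
    if cfg.residual_correlation == "iid" or cfg.resid_sd == 0:
        return rng.normal(0.0, cfg.resid_sd, size=(n, T))
    corr = np.exp(-dist / cfg.spatial_range_m)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    if cfg.residual_correlation == "spatial":
        return cfg.resid_sd * (L @ rng.normal(size=(n, T)))
    # separable: exponential in space x stationary AR(1) in time
    phi = cfg.ar_coef
    eps = np.empty((n, T))
    eps[:, 0] = L @ rng.normal(size=n)
    innov_sd = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        eps[:, t] = phi * eps[:, t - 1] + innov_sd * (L @ rng.normal(size=n))
    return cfg.resid_sd * eps


def gen_panel(cfg: PanelGenConfig):
    """Generate a :class:`PracticePanel` plus its ground-truth record.

    Returns
    -------
    panel : PracticePanel
    truth : dict
        Keys include ``monthly_temp`` (the lagged monthly driver d(t)),
        ``states`` (A_{p,t}, B_{p,t} paths), ``seasonal_path``, ``area_shock``
        (U_t), ``offset_path`` (intercept + temperature + harmonics + shock:
        the true area-wide monthly mean component), ``random_intercepts``,
        ``residuals`` and ``daily_temp``.
    """
    T, n, k = cfg.n_months, cfg.n_practices, cfg.k
    ss = np.random.SeedSequence(cfg.seed)
    s_temp, s_loc, s_state, s_cov, s_b, s_eps, s_u = ss.spawn(7)

    daily = gen_temperature(
        T,
        seed=s_temp,
        anchor=cfg.anchor,
        mean=cfg.temp_mean,
        amplitude=cfg.temp_amplitude,
        noise_sd=cfg.temp_noise_sd,
        lead_days=31,
    )
    d = lag_temperature(daily, cfg.temp_lag_days, anchor=cfg.anchor, n_months=T)
    locations = gen_locations(n, cfg.spatial_extent_m, seed=s_loc)
    xy = locations.to_numpy()
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))

    # harmonic-coefficient random walks
    rng_state = np.random.default_rng(s_state)
    t_idx = np.arange(1, T + 1)
    A = np.empty((k, T))
    B = np.empty((k, T))
    seasonal = np.zeros(T)
    for p in range(k):
        a0 = rng_state.normal(0.0, cfg.init_amplitude_sd[p])
        b0 = rng_state.normal(0.0, cfg.init_amplitude_sd[p])
        A[p] = a0 + np.cumsum(rng_state.normal(0.0, cfg.rw_sd[p], size=T))
        B[p] = b0 + np.cumsum(rng_state.normal(0.0, cfg.rw_sd[p], size=T))
        seasonal += A[p] * np.cos((p + 1) * OMEGA * t_idx) + B[p] * np.sin(
            (p + 1) * OMEGA * t_idx
        )

    shock = np.random.default_rng(s_u).normal(0.0, cfg.obs_sd, size=T)
    area_path = cfg.intercept + cfg.temp_coef * d.to_numpy() + seasonal
    offset_path = area_path + shock

    # covariates
    rng_cov = np.random.default_rng(s_cov)
    cov_names = tuple(cfg.covariate_effects)
    X = {}
    for name in cov_names:
        if name == "time_elapsed":
            X[name] = np.tile(t_idx.astype(float), (n, 1))
        else:
            X[name] = np.tile(
                _smooth_spatial_field(xy, cfg.spatial_extent_m, rng_cov)[:, None],
                (1, T),
            )
    effects = np.zeros((n, T))
    for name, coef in cfg.covariate_effects.items():
        effects += coef * X[name]

    b = np.random.default_rng(s_b).normal(0.0, cfg.rand_intercept_sd, size=n)
    eps = _residuals(cfg, dist, np.random.default_rng(s_eps))

    y = offset_path[None, :] + effects + b[:, None] + eps

    ids = locations.index.to_numpy()
    rec = {
        "practice_id": np.repeat(ids, T),
        "month": np.tile(t_idx, n),
        "log_rate": y.ravel(),
    }
    for name in cov_names:
        rec[name] = X[name].ravel()
    records = pd.DataFrame(rec)
    panel = PracticePanel(records, locations, covariate_names=cov_names)

    truth = {
        "config": asdict(cfg),
        "month": t_idx,
        "monthly_temp": d.to_numpy(),
        "states_A": A,
        "states_B": B,
        "seasonal_path": seasonal,
        "area_shock": shock,
        "area_path": area_path,
        "offset_path": offset_path,
        "covariate_effects": dict(cfg.covariate_effects),
        "random_intercepts": pd.Series(b, index=locations.index),
        "residuals": eps,
        "daily_temp": daily,
    }
    return panel, truth
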