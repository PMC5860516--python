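"""End-to-end driver: simulate (or load) -> stage-1 DHR -> stage-2 mixed model
-> correlation diagnostics, with every artifact written as plain text and a
single deterministic JSON summary."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .dhr import select_lag
from .diagnostics import permutation_envelope, st_variogram
from .mixed import RandomInterceptModel, blup_intervals, residual_checks
from .simulate import gen_panel, gen_temperature
from .temperature import lag_label

log = logging.getLogger("dhrpanel")


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(cfg: dio.RunConfig, out_dir=None) -> dict:
    """Run the full two-stage analysis and return the summary dict.

    Stages: (1) area-wide DHR with temperature-lag selection; (2) practice
    random-intercept mixed model with the stage-1 fitted curve as offset;
    (3) diagnostics — permutation-envelope variogram of the practice BLUPs and
    spatiotemporal variogram of the residuals.  All randomness is seeded by
    fanning out ``cfg.seed`` into named substreams.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = np.random.SeedSequence(cfg.seed)
    s_sim, s_perm = root_seed.spawn(2)

    summary: dict = {"seed": cfg.seed}

    # -- data ---------------------------------------------------------------
    if cfg.panel_path:
        _stage("load")
        panel = dio.read_panel(cfg.panel_path, cfg.locations_path)
        daily = dio.read_temperature(cfg.temperature_path)
        anchor = None
    else:
        _stage("simulate")
        sim_cfg = cfg.simulate
        if sim_cfg.seed is None:
            from dataclasses import replace

            sim_cfg = replace(
                sim_cfg, seed=int(s_sim.generate_state(1)[0] & 0x7FFFFFFF)
            )
        panel, truth = gen_panel(sim_cfg)
        daily = truth["daily_temp"]
        anchor = sim_cfg.anchor
        dio.write_panel(panel, out)
        dio.write_temperature(daily, out / dio.TEMPERATURE_FILE)
        dio.write_truth(truth, out / dio.TRUTH_FILE)
    summary["n_records"] = int(len(panel.records))
    summary["n_practices"] = int(panel.n_practices)
    summary["n_months"] = int(panel.n_months)

    # -- stage 1: area-wide DHR --------------------------------------------
    _stage("fit-dhr")
    area = panel.area_series()
    y = area.to_numpy()
    table, best_lag, fits = select_lag(
        y,
        daily,
        lags=cfg.lags,
        k=cfg.k,
        anchor=anchor,
        n_months=panel.n_months,
        dynamic_kwargs={"trend": cfg.stage1_trend, "n_starts": cfg.n_starts},
    )
    best = fits[best_lag]
    table.to_csv(out / "lag_selection.csv", index=False)
    offset_df = pd.DataFrame(
        {
            "month": area.index,
            "observed": y,
            "fitted": best.fitted_values_,
        }
    )
    for name in best.smoothed_states_.columns:
        offset_df[name] = best.smoothed_states_[name].to_numpy()
    offset_df.to_csv(out / "offset.csv", index=False)
    summary["stage1"] = {
        "selected_lag": lag_label(best_lag),
        "r2_table": {
            row["lag"]: {"dynamic": row["r2_dynamic"], "static": row["r2_static"]}
            for _, row in table.iterrows()
        },
        "r2_dynamic_best": best.r2_,
        "loglik": best.loglik_,
        "obs_variance": best.obs_variance_,
        "rw_variance": list(best.rw_variance_),
        "converged": best.converged_,
    }

    # -- stage 2: mixed model ----------------------------------------------
    _stage("fit-mixed")
    covs = list(cfg.covariates) if cfg.covariates is not None else list(panel.covariate_names)
    offset_by_month = pd.Series(best.fitted_values_, index=area.index)
    rec = panel.records
    model = RandomInterceptModel(method=cfg.method).fit(
        rec[covs],
        rec["log_rate"].to_numpy(),
        groups=rec["practice_id"].to_numpy(),
        offset=offset_by_month.reindex(rec["month"]).to_numpy(),
    )
    table1 = pd.DataFrame(
        {
            "term": model.fe_params_.index,
            "estimate": model.fe_params_.to_numpy(),
            "se": model.fe_se_.to_numpy(),
            "t_value": model.tvalues_.to_numpy(),
            "p_value": model.pvalues_.to_numpy(),
        }
    )
    table1.to_csv(out / "fixed_effects.csv", index=False)
    blups = blup_intervals(model, cfg.interval_level)
    blups.to_csv(out / "blups.csv")
    resid_df = rec[["practice_id", "month"]].copy()
    resid_df["easting"] = panel.locations.loc[resid_df["practice_id"], "easting"].to_numpy()
    resid_df["northing"] = panel.locations.loc[resid_df["practice_id"], "northing"].to_numpy()
    resid_df["residual"] = model.resid_
    resid_df.to_csv(out / "residuals.csv", index=False)
    summary["stage2"] = {
        "criterion": cfg.method,
        "fixed_effects": {
            t: {"estimate": e, "se": s, "t": tv, "p": pv}
            for t, e, s, tv, pv in zip(
                table1["term"], table1["estimate"], table1["se"], table1["t_value"], table1["p_value"]
            )
        },
        "sigma_b2": model.sigma_b2_,
        "sigma_e2": model.sigma_e2_,
        "boundary": model.boundary_,
    }

    # -- diagnostics ---------------------------------------------------------
    _stage("diagnose")
    edges = cfg.bin_edges_m()
    env = permutation_envelope(
        blups.sort_index()["blup"].to_numpy(),
        panel.locations.loc[blups.sort_index().index, ["easting", "northing"]].to_numpy(),
        n_perm=cfg.n_perm,
        seed=s_perm,
        bin_edges=edges,
    )
    env.to_frame().to_csv(out / "blup_variogram_envelope.csv", index=False)
    stv = st_variogram(
        model.resid_,
        panel.locations,
        rec["month"].to_numpy(),
        rec["practice_id"].to_numpy(),
        bin_edges=edges,
        time_lags=cfg.time_lags,
    )
    stv.to_frame().to_csv(out / "st_variogram.csv", index=False)
    checks = residual_checks(model, months=rec["month"].to_numpy())
    checks["acf"].to_csv(out / "residual_acf.csv")

    nonempty = env.observed.count > 0
    cells = np.isfinite(stv.mean)
    dist_mid = np.repeat(stv.bin_mid, len(stv.time_lags)).reshape(stv.mean.shape)
    lag_grid = np.tile(stv.time_lags, (stv.mean.shape[0], 1))
    from scipy.stats import spearmanr

    rho_dist = spearmanr(dist_mid[cells], stv.mean[cells]).statistic if cells.sum() > 2 else np.nan
    rho_lag = spearmanr(lag_grid[cells], stv.mean[cells]).statistic if cells.sum() > 2 else np.nan
    summary["diagnostics"] = {
        "envelope_bins": int(nonempty.sum()),
        "envelope_bins_inside": int((env.inside & nonempty).sum()),
        "envelope_all_inside": env.all_inside,
        "st_rank_corr_distance": float(rho_dist),
        "st_rank_corr_lag": float(rho_lag),
        "max_abs_resid_acf_lag1": float(
            np.nanmax(np.abs(checks["acf"]["lag1"])) if "lag1" in checks["acf"] else np.nan
        ),
    }

    dio.write_json(summary, out / "summary.json")
    return summary
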