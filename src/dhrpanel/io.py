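"""Readers/writers for the plain-text artifact formats, plus run configuration.

Everything is UTF-8 delimited text ("." decimal separator): long-format panel
records, a locations table, daily temperature, and JSON sidecars for ground
truth and run summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import PracticePanel
from .simulate import PanelGenConfig

PANEL_FILE = "panel.csv"
LOCATIONS_FILE = "locations.csv"
TEMPERATURE_FILE = "daily_temperature.csv"
TRUTH_FILE = "truth.json"


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def write_panel(panel: PracticePanel, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.records.to_csv(out / PANEL_FILE, index=False)
    panel.locations.to_csv(out / LOCATIONS_FILE)


def read_panel(panel_path, locations_path, covariates=None) -> PracticePanel:
    """Read and validate a long-format panel plus its locations table.

    ``covariates`` names the covariate columns; defaults to every column other
    than the required ones.
    """
    records = pd.read_csv(panel_path)
    for col in ("practice_id", "month", "log_rate"):
        if col not in records.columns:
            raise ValueError(f"panel file is missing required column {col!r}")
    locations = pd.read_csv(locations_path)
    if "practice_id" not in locations.columns:
        raise ValueError("locations file is missing required column 'practice_id'")
    for col in ("easting", "northing"):
        if col not in locations.columns:
            raise ValueError(f"locations file is missing required column {col!r}")
    locations = locations.set_index("practice_id")
    if covariates is None:
        covariates = [
            c for c in records.columns if c not in ("practice_id", "month", "log_rate")
        ]
    return PracticePanel(records, locations, covariate_names=tuple(covariates))


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def write_temperature(daily: pd.Series, path) -> None:
    df = pd.DataFrame({"date": daily.index.strftime("%Y-%m-%d"), "temp_c": daily.to_numpy()})
    df.to_csv(path, index=False)


def read_temperature(path) -> pd.Series:
    df = pd.read_csv(path)
    for col in ("date", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"temperature file is missing required column {col!r}")
    s = pd.Series(df["temp_c"].to_numpy(), index=pd.DatetimeIndex(pd.to_datetime(df["date"])))
    return s.sort_index()


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {"index": _jsonable(list(obj.index)), "values": _jsonable(obj.to_list())}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_truth(truth: dict, path) -> None:
    slim = {k: v for k, v in truth.items() if k != "daily_temp"}
    write_json(slim, path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``simulate`` holds the generator settings; when ``panel_path`` is given
    the pipeline loads data from disk instead of simulating.
    """

    seed: int = 0
    out_dir: str = "run"

    # data source
    simulate: PanelGenConfig = field(default_factory=PanelGenConfig)
    panel_path: str | None = None
    locations_path: str | None = None
    temperature_path: str | None = None

    # stage 1
    k: int = 2
    lags: tuple = (0, 7, 14, 21, "1m")
    stage1_trend: bool = False
    n_starts: int = 5

    # stage 2
    covariates: tuple | None = None  # None -> all panel covariates
    method: str = "reml"
    interval_level: float = 0.95

    # diagnostics
    n_perm: int = 99
    bin_km: float = 1.0
    max_km: float = 20.0
    time_lags: tuple = (0, 1, 2, 3)

    def bin_edges_m(self) -> np.ndarray:
        nb = int(round(self.max_km / self.bin_km))
        return np.arange(nb + 1) * self.bin_km * 1000.0


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", {}) or {}
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "simulate"})
    if isinstance(sim, dict):
        cfg.simulate = PanelGenConfig(**sim)
    if "seed" in raw and cfg.simulate.seed is None:
        cfg.simulate.seed = cfg.seed
    if isinstance(cfg.lags, list):
        cfg.lags = tuple(cfg.lags)
    if isinstance(cfg.time_lags, list):
        cfg.time_lags = tuple(cfg.time_lags)
    if isinstance(cfg.covariates, list):
        cfg.covariates = tuple(cfg.covariates)
    return cfg
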