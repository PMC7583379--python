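"""File formats: delimited readers/writers and run manifests.

All tables are tab-separated text with a header line; every writer
round-trips losslessly through its reader.  Manifests record the seed,
configuration hash, and package version so any run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from lakeshift.grid import Hypsograph
from lakeshift.parameters import ParameterSet
from lakeshift.synthetic import ObservationSet

__all__ = [
    "read_hypsograph", "write_hypsograph",
    "read_meteorology", "write_meteorology",
    "read_inflow", "write_inflow",
    "read_observations", "write_observations",
    "read_parameters", "write_parameters",
    "write_run_diagnostics", "write_load_response",
    "write_manifest", "config_hash",
]

METEO_COLS = ["time", "air_temp", "pressure", "dewpoint", "cloud", "wind_u", "wind_v"]
INFLOW_COLS = ["time", "inlet", "discharge_m3s", "nh4", "no3", "po4", "org_n", "org_p"]
OBS_COLS = ["variable", "time", "day", "sample_depth_m", "value", "error_fraction"]


def write_hypsograph(hyps: Hypsograph, path) -> None:
    pd.DataFrame({"level_m": hyps.levels, "area_m2": hyps.areas}).to_csv(
        path, sep="\t", index=False)


def read_hypsograph(path) -> Hypsograph:
    df = pd.read_csv(path, sep="\t")
    if not {"level_m", "area_m2"}.issubset(df.columns):
        raise ValueError("hypsograph file needs columns level_m, area_m2")
    return Hypsograph(levels=df["level_m"].to_numpy(float),
                      areas=df["area_m2"].to_numpy(float))


def write_meteorology(meteo: pd.DataFrame, path) -> None:
    out = meteo[METEO_COLS].copy()
    out["time"] = pd.DatetimeIndex(out["time"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, sep="\t", index=False)


def read_meteorology(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METEO_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"meteorology file missing columns {sorted(missing)}")
    df["time"] = pd.to_datetime(df["time"])
    return df


def write_inflow(inflow: pd.DataFrame, path) -> None:
    out = inflow[INFLOW_COLS].copy()
    out["time"] = pd.DatetimeIndex(out["time"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, sep="\t", index=False)


def read_inflow(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(INFLOW_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"inflow file missing columns {sorted(missing)}")
    df["time"] = pd.to_datetime(df["time"])
    return df


def write_observations(obs: ObservationSet, path) -> None:
    out = obs.records.copy()
    if "time" in out.columns:
        out["time"] = pd.DatetimeIndex(out["time"]).strftime("%Y-%m-%dT%H:%M:%S")
    cols = [c for c in OBS_COLS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_observations(path) -> ObservationSet:
    df = pd.read_csv(path, sep="\t")
    if "time" in df.columns:
        df["time"] = pd.to_datetime(df["time"])
    return ObservationSet(df)


def write_parameters(params: ParameterSet, path) -> None:
    params.to_frame().to_csv(path, sep="\t", index=False)


def read_parameters(path) -> ParameterSet:
    return ParameterSet.from_frame(pd.read_csv(path, sep="\t"))


def write_run_diagnostics(result, path) -> None:
    """Tidy (day, layer, variable, value) table of daily layer diagnostics."""
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_load_response(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, *, seed, config, extra=None) -> dict:
    from lakeshift import __version__

    manifest = {
        "package": "lakeshift",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
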