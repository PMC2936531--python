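"""Tabular and manifest writers.

Trajectories are tab-separated with a fixed, documented column order and a
trailing newline; manifests are JSON with sorted keys.  Together with the
config file and seed, a manifest is sufficient to reproduce a run exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import SimulationParams

__all__ = ["write_trajectory", "read_trajectory", "write_manifest",
           "read_manifest", "write_table"]

TRAJECTORY_COLUMNS = ["t", "N", "N_competent", "mean_ones", "births",
                      "deaths", "switch_in", "switch_out", "recombinations"]


def write_trajectory(traj, path) -> None:
    """Write a trajectory recarray (or DataFrame) as TSV."""
    df = pd.DataFrame({c: np.asarray(traj[c]) for c in TRAJECTORY_COLUMNS})
    tmp = Path(str(path) + ".tmp")
    try:
        df.to_csv(tmp, sep="\t", index=False, lineterminator="\n")
        tmp.replace(path)
    finally:
        tmp.unlink(missing_ok=True)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trajectory column(s) {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    tmp = Path(str(path) + ".tmp")
    try:
        df.to_csv(tmp, sep="\t", index=False, lineterminator="\n")
        tmp.replace(path)
    finally:
        tmp.unlink(missing_ok=True)


def write_manifest(path, params: SimulationParams, seed: int,
                   termination: str | None = None, **extra) -> None:
    data = {
        "engine_version": __version__,
        "params": params.to_dict(),
        "seed": seed,
        "termination": termination,
    }
    data.update(extra)
    tmp = Path(str(path) + ".tmp")
    try:
        tmp.write_text(json.dumps(data, sort_keys=True, indent=2, default=_json_default)
                       + "\n")
        tmp.replace(path)
    finally:
        tmp.unlink(missing_ok=True)


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
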