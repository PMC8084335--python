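"""Tabular file formats and configuration loading.

Everything is plain delimited text (CSV with header) for diff-ability.
Internally all quantities are SI; millimetres appear only at reporting
boundaries (the ``*_mm`` columns of result tables).

The trajectory table holds one row per recorded sample with columns
``participant, condition, phase, trial, t_s, x_m, y_m, vx_ms, vy_ms,
fx_N, fy_N``; (participant, condition, trial, t_s) must be unique and
``t_s`` strictly increasing within a trial.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fields import ChannelSpec, FieldSpec
from .trajectory import Trajectory

TRAJECTORY_COLUMNS = [
    "participant", "condition", "phase", "trial",
    "t_s", "x_m", "y_m", "vx_ms", "vy_ms", "fx_N", "fy_N",
]


def write_trajectory_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    df.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)


def read_trajectory_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed trajectory table {path}: missing columns {missing}")
    validate_trajectory_table(df)
    return df


def validate_trajectory_table(df: pd.DataFrame) -> None:
    """Check uniqueness and time monotonicity; report the offending row."""
    key = ["participant", "condition", "trial", "t_s"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"duplicate (participant, condition, trial, t_s) at row {row}")
    for (_, _, _), g in df.groupby(["participant", "condition", "trial"], sort=False):
        t = g["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = int(g.index[int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1])
            raise ValueError(f"t_s not strictly increasing at row {row}")


def trajectories_from_table(df: pd.DataFrame):
    """Yield (participant, condition, phase, trial, Trajectory) per trial."""
    for (p, c, tr), g in df.groupby(["participant", "condition", "trial"], sort=True):
        g = g.sort_values("t_s")
        yield p, c, g["phase"].iloc[0], tr, Trajectory(
            times=g["t_s"].to_numpy(),
            positions=g[["x_m", "y_m"]].to_numpy(),
            velocities=g[["vx_ms", "vy_ms"]].to_numpy(),
            applied_forces=g[["fx_N", "fy_N"]].to_numpy(),
        )


def field_to_dict(spec: FieldSpec) -> dict:
    return {"kind": spec.kind.value, "b1": spec.b1, "k1": spec.k1, "k2": spec.k2}


def field_from_dict(d: dict) -> FieldSpec:
    return FieldSpec(kind=d["kind"], b1=d.get("b1", 0.0), k1=d.get("k1", 0.0),
                     k2=d.get("k2", 0.0))


def channel_to_dict(spec: ChannelSpec) -> dict:
    return {"stiffness": spec.stiffness, "damping": spec.damping,
            "activation_y": spec.activation_y}


def channel_from_dict(d: dict) -> ChannelSpec:
    return ChannelSpec(**d)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for run logging."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_result_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
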