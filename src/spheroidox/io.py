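"""Measurement-table and trajectory I/O, configuration, provenance.

One CSV dialect is used throughout.  Measurement tables are long-format with
header ``spheroid_id, day, condition, R_o_um, R_n_um, R_i_um, R_p_um``; an
empty cell means the measurement is missing (not zero — a structural radius
of 0 means the region has not formed and is written as 0).  Trajectory files
carry ``day, R_o_um, R_i_um, R_n_um, phase`` plus, for switching models, the
predicted core radius, core volume and the instantaneous parameter values.
Floating-point output format is pinned so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .adaptation import SwitchingTrajectory
from .greenspan import Trajectory

__all__ = [
    "MEASUREMENT_COLUMNS",
    "RunConfig",
    "read_measurements",
    "write_measurements",
    "validate_measurements",
    "area_to_radius",
    "write_trajectory",
    "provenance_record",
]

MEASUREMENT_COLUMNS = ["spheroid_id", "day", "condition",
                       "R_o_um", "R_n_um", "R_i_um", "R_p_um"]
_REQUIRED = ["spheroid_id", "day", "condition", "R_o_um"]
FLOAT_FORMAT = "%.6f"


def area_to_radius(A) -> Union[float, np.ndarray]:
    """Equivalent circular radius from a cross-section area, r = sqrt(A/pi)."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("area must be non-negative")
    r = np.sqrt(A / math.pi)
    return float(r) if r.ndim == 0 else r


def read_measurements(path) -> pd.DataFrame:
    """Read a radial-measurement table; empty cells become NaN (missing).

    Raises with the missing column names if the header is invalid; malformed
    numeric rows are reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"spheroid_id": str, "condition": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {', '.join(missing)}")
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad_lines = []
    for col in ["day", "R_o_um", "R_n_um", "R_i_um", "R_p_um"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            bad_lines += [f"line {i + 2}: non-numeric {col}={df.loc[i, col]!r}"
                          for i in df.index[bad]]
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path}: malformed rows: " + "; ".join(bad_lines))
    return df[MEASUREMENT_COLUMNS + [c for c in df.columns if c not in MEASUREMENT_COLUMNS]]


def write_measurements(df: pd.DataFrame, path) -> None:
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Structural-consistency report: one row per offending table row.

    Checks R_n <= R_o, R_i <= R_o, R_p <= R_o, non-negative radii and
    non-negative days.  Offending rows are reported, never dropped.
    """
    issues = []
    for i, row in df.iterrows():
        R_o = row["R_o_um"]
        for col, label in (("R_n_um", "R_n > R_o"), ("R_i_um", "R_i > R_o"),
                           ("R_p_um", "R_p > R_o")):
            v = row.get(col)
            if pd.notna(v) and pd.notna(R_o) and v > R_o:
                issues.append({"row": i, "spheroid_id": row["spheroid_id"],
                               "issue": label, "value": float(v), "R_o_um": float(R_o)})
        for col in ["day", "R_o_um", "R_n_um", "R_i_um", "R_p_um"]:
            v = row.get(col)
            if pd.notna(v) and v < 0:
                issues.append({"row": i, "spheroid_id": row["spheroid_id"],
                               "issue": f"negative {col}", "value": float(v),
                               "R_o_um": float(R_o) if pd.notna(R_o) else np.nan})
    return pd.DataFrame(issues, columns=["row", "spheroid_id", "issue", "value", "R_o_um"])


def write_trajectory(traj: Union[Trajectory, SwitchingTrajectory], path) -> None:
    """Write a solved trajectory as delimited text (pinned float format)."""
    cols = {
        "day": traj.t, "R_o_um": traj.R_o, "R_i_um": traj.R_i, "R_n_um": traj.R_n,
        "phase": [p.value for p in traj.phase],
    }
    if isinstance(traj, SwitchingTrajectory):
        cols.update({
            "R_n_plus_um": traj.R_n_plus, "V_n_um3": traj.V_n, "a_t": traj.a_t,
            "s_t": traj.s_t, "lambda_t": traj.lam_t, "Rbar_t_um": traj.Rbar_t,
        })
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class RunConfig:
    """Run settings: model selection, constants, bounds, solver and sampler
    options, seed.  Round-trips losslessly through YAML."""

    model: str = "greenspan"
    seed: int = 0
    t_end: float = 8.0
    t_s: float = 2.0
    p_inf_pre: float = 21.0
    p_inf_post: float = 2.0
    p_hyp: float = 1.5
    percent_to_mmhg: float = 7.6
    constants: dict = field(default_factory=dict)     # e.g. {"k": ..., "Omega": ...}
    params: dict = field(default_factory=dict)        # model parameter values
    bounds: dict = field(default_factory=dict)        # name -> [lo, hi]
    solver: dict = field(default_factory=lambda: {"dt": 0.005, "rtol": 1e-8, "atol": 1e-10})
    mcmc: dict = field(default_factory=lambda: {"n_chains": 4, "n_samples": 20000,
                                                "burn_in": 5000})

    _KNOWN = ("model", "seed", "t_end", "t_s", "p_inf_pre", "p_inf_post", "p_hyp",
              "percent_to_mmhg", "constants", "params", "bounds", "solver", "mcmc")

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = [k for k in raw if k not in cls._KNOWN]
        if unknown:
            raise KeyError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._KNOWN}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def provenance_record(config: RunConfig, extra: Optional[dict] = None) -> dict:
    """Reproducibility stamp: config hash, seed, package and platform versions."""
    from . import __version__

    rec = {
        "config_sha256_16": config.digest(),
        "seed": config.seed,
        "spheroidox_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
    }
    if extra:
        rec.update(extra)
    return rec
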