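"""File formats and run configuration.

CSV conventions: comma-separated, '.' decimal, UTF-8, header row mandatory.
Positions are stored in millimeters and times in seconds (internal code uses
SI meters).  Schemas:

* signal CSV       — ``time_s, x_mm, y_mm, z_mm`` (or ``time_s, z`` for a
  single-coordinate tapping take);
* frames CSV       — ``time_s, v_01 … v_NN`` (one voltage frame per row);
* trajectory CSV   — ``time_s, x_mm, y_mm, z_mm, nx, ny, nz, cost, converged``;
* array JSON       — receiver positions (mm), normals, windings, radii plus
  transmitter parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coils import CoilArray, Pose, ReceiverCoil, TransmitterSpec, VoltageFrame
from .estimator import Trajectory

__all__ = [
    "ParseError",
    "RunConfig",
    "write_signal_csv",
    "read_signal_csv",
    "write_frames_csv",
    "read_frames_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "array_to_json",
    "array_from_json",
    "load_default_array_config",
    "write_json",
    "read_json",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one analysis run; defaults follow the bench
    protocol (62 Sa/s, 2.5 / 1 Hz cutoffs, 30 % windows with 50 % overlap,
    k = 10 neighbors, 5 folds)."""

    rate: float = 62.0
    snr_db: float | None = 20.0
    seed: int = 0
    tremor_cutoff_hz: float = 2.5
    sm_cutoff_hz: float = 1.0
    window_frac: float = 0.3
    overlap: float = 0.5
    knn_k: int = 10
    cv_folds: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


def _check_no_missing(df: pd.DataFrame, path) -> None:
    bad = df.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: malformed or incomplete row at line {line}")


def _read_csv(path, required: list) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (line 1)")
    _check_no_missing(df[required], path)
    return df


# ---------------------------------------------------------------- signals

def write_signal_csv(path, times, values_mm, columns=("x_mm", "y_mm", "z_mm")) -> None:
    """Write a coordinate series; ``values_mm`` is (n, len(columns)) or (n,)."""
    values_mm = np.atleast_2d(np.asarray(values_mm, dtype=float))
    if values_mm.shape[0] == 1 and len(columns) == 1:
        values_mm = values_mm.T
    df = pd.DataFrame({"time_s": np.asarray(times, dtype=float)})
    for i, c in enumerate(columns):
        df[c] = values_mm[:, i]
    df.to_csv(path, index=False)


def read_signal_csv(path, columns=("x_mm", "y_mm", "z_mm")):
    """Return (times, values) with values shaped (n, len(columns))."""
    df = _read_csv(path, ["time_s", *columns])
    return df["time_s"].to_numpy(), df[list(columns)].to_numpy()


# ----------------------------------------------------------------- frames

def _voltage_columns(n: int) -> list:
    return [f"v_{i + 1:02d}" for i in range(n)]


def write_frames_csv(path, frames) -> None:
    frames = list(frames)
    n = len(frames[0])
    cols = _voltage_columns(n)
    df = pd.DataFrame([f.voltages for f in frames], columns=cols)
    df.insert(0, "time_s", [f.timestamp for f in frames])
    df.to_csv(path, index=False)


def read_frames_csv(path, n_channels: int = 24):
    df = _read_csv(path, ["time_s", *_voltage_columns(n_channels)])
    cols = _voltage_columns(n_channels)
    return [
        VoltageFrame(timestamp=float(row["time_s"]),
                     voltages=row[cols].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]


# ------------------------------------------------------------- trajectory

def write_trajectory_csv(path, traj: Trajectory, costs=None, converged=None) -> None:
    n = len(traj)
    pos = traj.positions * 1e3
    ori = traj.orientations
    df = pd.DataFrame(
        {
            "time_s": traj.times,
            "x_mm": pos[:, 0],
            "y_mm": pos[:, 1],
            "z_mm": pos[:, 2],
            "nx": ori[:, 0],
            "ny": ori[:, 1],
            "nz": ori[:, 2],
            "cost": np.zeros(n) if costs is None else np.asarray(costs, dtype=float),
            "converged": np.ones(n, bool) if converged is None else np.asarray(converged, bool),
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path, rate: float = 62.0) -> Trajectory:
    df = _read_csv(path, ["time_s", "x_mm", "y_mm", "z_mm", "nx", "ny", "nz"])
    poses = []
    for _, row in df.iterrows():
        n = np.array([row["nx"], row["ny"], row["nz"]], dtype=float)
        n = n / np.linalg.norm(n)
        poses.append(
            Pose(
                position=np.array([row["x_mm"], row["y_mm"], row["z_mm"]]) * 1e-3,
                orientation=n,
            )
        )
    return Trajectory(times=df["time_s"].to_numpy(), poses=poses, rate=rate)


# ------------------------------------------------------------- array JSON

def array_to_json(array: CoilArray, path=None) -> dict:
    """Serialize an array geometry; writes to ``path`` if given."""
    tx = array.transmitter
    obj = {
        "transmitter": {
            "windings": tx.windings,
            "radius_mm": tx.radius * 1e3,
            "current_a_rms": tx.current,
            "frequency_hz": tx.frequency,
        },
        "receivers": [
            {
                "position_mm": (r.position * 1e3).tolist(),
                "normal": r.normal.tolist(),
                "windings": r.windings,
                "radius_mm": r.radius * 1e3,
            }
            for r in array.receivers
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=1))
    return obj


def array_from_json(source) -> CoilArray:
    """Load an array geometry from a path, JSON string or dict."""
    if isinstance(source, dict):
        obj = source
    else:
        p = Path(source)
        obj = json.loads(p.read_text() if p.exists() else str(source))
    t = obj["transmitter"]
    tx = TransmitterSpec(
        windings=int(t["windings"]),
        radius=float(t["radius_mm"]) * 1e-3,
        current=float(t["current_a_rms"]),
        frequency=float(t["frequency_hz"]),
    )
    rxs = tuple(
        ReceiverCoil(
            position=np.asarray(r["position_mm"], dtype=float) * 1e-3,
            normal=np.asarray(r["normal"], dtype=float),
            windings=int(r["windings"]),
            radius=float(r["radius_mm"]) * 1e-3,
        )
        for r in obj["receivers"]
    )
    return CoilArray(receivers=rxs, transmitter=tx)


def load_default_array_config() -> CoilArray:
    """Load the bundled default-geometry JSON."""
    text = resources.files("magtremor.data").joinpath("default_array.json").read_text()
    return array_from_json(json.loads(text))


# ------------------------------------------------------------------ JSON

def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
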