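"""Delimited-table and HDF5 I/O plus run manifests.

Trajectories travel as CSV with columns (cell_id, time_s, vx_um_s[, x, y, z,
state]); activity traces as (cell_id, time_s, activity); generic series as
(time_s, value). Every CLI run writes a JSON manifest (config hash, seed,
package version) beside its outputs so tables are traceable.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "trajectories_to_frame", "frame_to_trajectories", "write_trajectories",
    "read_trajectories", "write_traces", "read_traces", "write_series",
    "read_series", "write_manifest", "config_hash", "write_table_csv",
    "write_series_h5", "read_series_h5",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path: str | Path, command: str, seed, config) -> Path:
    """Write a JSON run manifest next to the outputs; returns its path."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "package_version": __version__,
        "python": platform.python_version(),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Stack trajectories into a long table with one row per sample."""
    frames = []
    for cid, traj in enumerate(trajectories):
        d = traj.positions.shape[1] if traj.positions.size else 0
        cols = {"cell_id": cid, "time_s": traj.times, "vx_um_s": traj.vx,
                "state": traj.state.astype(int)}
        for ax, name in zip(range(d), ("x", "y", "z")):
            cols[name] = traj.positions[:, ax]
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    axes = [c for c in ("x", "y", "z") if c in df.columns]
    for _, sub in df.groupby("cell_id", sort=True):
        pos = (sub[axes].to_numpy() if axes
               else np.zeros((len(sub), 1)))
        state = (sub["state"].to_numpy().astype(bool) if "state" in sub.columns
                 else np.ones(len(sub), dtype=bool))
        out.append(Trajectory(times=sub["time_s"].to_numpy(),
                              positions=pos,
                              vx=sub["vx_um_s"].to_numpy(),
                              state=state))
    return out


def write_table_csv(df: pd.DataFrame, path: str | Path,
                    header_comment: str = "") -> Path:
    """CSV with an optional '#'-prefixed header comment (units, hashes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in filter(None, header_comment.split("\n")):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return path


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trajectories(trajectories, path, header_comment="units: time_s s, vx_um_s um/s, positions um"):
    return write_table_csv(trajectories_to_frame(trajectories), path, header_comment)


def read_trajectories(path) -> list[Trajectory]:
    return frame_to_trajectories(_read_csv(path))


def write_traces(traces: Sequence[np.ndarray], dt: float, path,
                 header_comment="units: time_s s, activity dimensionless") -> Path:
    frames = [pd.DataFrame({"cell_id": cid, "time_s": np.arange(tr.size) * dt,
                            "activity": tr})
              for cid, tr in enumerate(traces)]
    return write_table_csv(pd.concat(frames, ignore_index=True), path,
                           header_comment)


def read_traces(path) -> tuple[list[np.ndarray], float]:
    df = _read_csv(path)
    traces = [sub["activity"].to_numpy()
              for _, sub in df.groupby("cell_id", sort=True)]
    t = df[df.cell_id == df.cell_id.iloc[0]]["time_s"].to_numpy()
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    return traces, dt


def write_series(times: np.ndarray, values: np.ndarray, path,
                 header_comment="") -> Path:
    return write_table_csv(pd.DataFrame({"time_s": times, "value": values}),
                           path, header_comment)


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path)
    return df["time_s"].to_numpy(), df["value"].to_numpy()


def write_series_h5(times, values, path, *, dt: float, units: str,
                    channel: str, seed=None) -> Path:
    """HDF5 mirror of a (time, value) series with dataset attributes."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("series")
        grp.create_dataset("time", data=np.asarray(times))
        grp.create_dataset("value", data=np.asarray(values))
        grp.attrs["dt"] = dt
        grp.attrs["units"] = units
        grp.attrs["channel"] = channel
        if seed is not None:
            grp.attrs["seed"] = seed
    return path


def read_series_h5(path) -> tuple[np.ndarray, np.ndarray, dict]:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh["series"]
        return grp["time"][...], grp["value"][...], dict(grp.attrs)
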