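"""Delimited-text and JSON I/O for every pipeline artifact.

All tabular files are comma-separated UTF-8 with a single header row whose
column names carry the units (``t_s``, ``x_mm``, ``v_mv``, ...); arena
coordinates are millimetres with the source at the origin and x positive
downwind.  Structured metadata (configs, truths, manifests) is JSON.
Writers use fixed float formatting so identical data produces identical
bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EncounterSeries, Trajectory
from .eag import EAGTrace, IntensitySeries
from .infotaxis import EntropyTrace, SourcePosterior

__all__ = [
    "read_trajectory", "write_trajectory",
    "read_eag", "write_eag",
    "read_encounters", "write_encounters",
    "write_entropy_trace", "read_entropy_trace",
    "write_posterior",
    "read_config", "write_json",
]

_FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    """A file does not match its declared schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"found {list(df.columns)}")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read ``t_s,x_mm,y_mm[,heading_deg]``; times must be strictly
    increasing (the offending row is named otherwise)."""
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "x_mm", "y_mm"], path)
    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise SchemaError(
                f"{path}: time not strictly increasing at row "
                f"{int(bad[0]) + 2} (t={t[bad[0] + 1]})")
    heading = (df["heading_deg"].to_numpy(dtype=float)
               if "heading_deg" in df.columns else None)
    return Trajectory(t, df["x_mm"].to_numpy(dtype=float),
                      df["y_mm"].to_numpy(dtype=float), heading)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    cols = {"t_s": traj.t, "x_mm": traj.x, "y_mm": traj.y}
    if traj.heading_deg is not None:
        cols["heading_deg"] = traj.heading_deg
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_eag(path: str | Path, fs: float = 1000.0) -> EAGTrace:
    """Read ``t_s,v_mv`` and validate uniform sampling at ``fs``; a gap
    is reported with the time of its first occurrence."""
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "v_mv"], path)
    t = df["t_s"].to_numpy(dtype=float)
    v = df["v_mv"].to_numpy(dtype=float)
    dt = np.diff(t)
    nominal = 1.0 / fs
    bad = np.flatnonzero(np.abs(dt - nominal) > 0.01 * nominal)
    if bad.size:
        raise SchemaError(
            f"{path}: sampling gap at t={t[bad[0]]:.4f}s "
            f"({dt[bad[0]] * 1e3:.2f} ms, expected {nominal * 1e3:.2f} ms)")
    # rebuild the time base exactly uniform (text round-trip jitter)
    t_uniform = t[0] + np.arange(t.size) / fs
    return EAGTrace(t=t_uniform, v=v, fs=fs)


def write_eag(path: str | Path, trace: EAGTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "v_mv": trace.v}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_encounters(path: str | Path, t_start: float | None = None,
                    t_end: float | None = None) -> EncounterSeries:
    """Read ``t_s[,amplitude_mv][,intensity][,x_mm,y_mm]``."""
    df = pd.read_csv(path)
    _require_columns(df, ["t_s"], path)
    times = df["t_s"].to_numpy(dtype=float)
    amps = (df["amplitude_mv"].to_numpy(dtype=float)
            if "amplitude_mv" in df.columns else None)
    pos = None
    if "x_mm" in df.columns and "y_mm" in df.columns:
        pos = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    if t_start is None:
        t_start = float(times[0]) if times.size else 0.0
    if t_end is None:
        t_end = float(times[-1]) if times.size else 0.0
    return EncounterSeries(times, t_start, t_end, positions_mm=pos,
                           amplitudes_mv=amps)


def write_encounters(path: str | Path, enc: EncounterSeries,
                     intensity: IntensitySeries | None = None) -> None:
    cols: dict = {"t_s": enc.times}
    if enc.amplitudes_mv is not None:
        cols["amplitude_mv"] = enc.amplitudes_mv
    if intensity is not None:
        cols["intensity"] = intensity.intensity
    if enc.positions_mm is not None:
        cols["x_mm"] = enc.positions_mm[:, 0]
        cols["y_mm"] = enc.positions_mm[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_entropy_trace(path: str | Path, trace: EntropyTrace) -> None:
    """Columns ``t_s,S_nats,S_rel,est_x_mm,est_y_mm[,est_err_mm]``."""
    cols = {
        "t_s": trace.eval_times,
        "S_nats": trace.S,
        "S_rel": trace.S_rel,
        "est_x_mm": trace.est_source_m[:, 0] * 1000.0,
        "est_y_mm": trace.est_source_m[:, 1] * 1000.0,
    }
    if trace.est_error_m is not None:
        cols["est_err_mm"] = trace.est_error_m * 1000.0
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_entropy_trace(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "S_nats", "S_rel"], path)
    return df


def write_posterior(path: str | Path, post: SourcePosterior) -> None:
    """Long-format posterior: ``x_mm,y_mm,prob`` per grid cell."""
    centers_mm = post.grid.centers * 1000.0
    pd.DataFrame({"x_mm": centers_mm[:, 0], "y_mm": centers_mm[:, 1],
                  "prob": post.probs}).to_csv(
        path, index=False, float_format="%.9g")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
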