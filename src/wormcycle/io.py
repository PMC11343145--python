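"""Readers and writers for the package's on-disk formats.

CSV dialect everywhere: comma-separated, UTF-8, one header row, '.' decimal.
Trace tables are long-format (frame, roi, intensity, background); midlines
are long-format (frame, point, x_um, y_um).  Image stacks are TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import MidlineTrack
from .synthgen import RoiTraceSet


def write_trace_csv(path: str | Path, traces: RoiTraceSet) -> None:
    frames = np.arange(traces.n_frames)
    parts = []
    for name in traces.names:
        parts.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "roi": name,
                    "intensity": traces.traces[name],
                    "background": traces.background,
                }
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path: str | Path, fps: float) -> RoiTraceSet:
    df = pd.read_csv(path)
    required = {"frame", "roi", "intensity", "background"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = {}
    background = None
    for name, sub in df.groupby("roi", sort=False):
        sub = sub.sort_values("frame")
        traces[str(name)] = sub["intensity"].to_numpy(dtype=float)
        background = sub["background"].to_numpy(dtype=float)
    return RoiTraceSet(traces, background, fps)


def write_midline_csv(path: str | Path, track: MidlineTrack) -> None:
    f, p = np.meshgrid(
        np.arange(track.n_frames), np.arange(track.n_points), indexing="ij"
    )
    pd.DataFrame(
        {
            "frame": f.ravel(),
            "point": p.ravel(),
            "x_um": track.coords[:, :, 0].ravel(),
            "y_um": track.coords[:, :, 1].ravel(),
        }
    ).to_csv(path, index=False)


def read_midline_csv(path: str | Path, fps: float, um_per_px: float = 1.0) -> MidlineTrack:
    df = pd.read_csv(path)
    required = {"frame", "point"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if {"x_um", "y_um"} <= set(df.columns):
        xcol, ycol, scale = "x_um", "y_um", 1.0
    elif {"x", "y"} <= set(df.columns):
        xcol, ycol, scale = "x", "y", um_per_px
    else:
        raise ValueError(f"{path}: no coordinate columns (x_um/y_um or x/y)")
    df = df.sort_values(["frame", "point"])
    n_frames = df["frame"].nunique()
    n_points = df["point"].nunique()
    if len(df) != n_frames * n_points:
        raise ValueError(f"{path}: ragged midline table")
    coords = np.empty((n_frames, n_points, 2))
    coords[:, :, 0] = df[xcol].to_numpy().reshape(n_frames, n_points) * scale
    coords[:, :, 1] = df[ycol].to_numpy().reshape(n_frames, n_points) * scale
    return MidlineTrack(coords, fps, note=str(path))


def read_tiff_stack(path: str | Path) -> np.ndarray:
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_tiff_stack(path: str | Path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_json_report(path: str | Path, report: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=default)
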