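"""File formats and run configuration.

Native dialects are plain CSV: tracks as ``track_id, frame, x_um, y_um``
with the frame interval in a ``# frame_interval_s = X`` header comment,
contours as ``cell_id, vertex_index, x_um, y_um``.  A simplified
TrackMate-export dialect (``TRACK_ID, FRAME, POSITION_X, POSITION_Y``,
positions in pixels) maps onto the same Track type.  Configs are flat
YAML key-value files with strict key checking.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contours import CellContour
from .tracks import MIN_FIT_FRAMES, Track

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_contours",
    "write_contours",
    "fit_eligible_tracks",
    "load_config",
    "write_resolved_config",
    "CONFIG_KEYS",
]

log = logging.getLogger("mrebalign")

_NATIVE_COLS = ["track_id", "frame", "x_um", "y_um"]
_TRACKMATE_COLS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]


def _header_keys(path: Path) -> dict[str, str]:
    keys = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                keys[k.strip()] = v.strip()
    return keys


def read_tracks(path, dialect: str = "native", frame_interval: float | None = None,
                pixel_size: float | None = None) -> list[Track]:
    """Read a track table into Track records, sorted by id then frame.

    ``pixel_size`` (um/px) converts pixel-based positions to um for the
    trackmate_export dialect; the native dialect is already in um.
    """
    path = Path(path)
    if dialect == "native":
        cols = _NATIVE_COLS
        header = _header_keys(path)
        if frame_interval is None and "frame_interval_s" in header:
            frame_interval = float(header["frame_interval_s"])
    elif dialect == "trackmate_export":
        cols = _TRACKMATE_COLS
    else:
        raise ValueError(f"unknown track dialect: {dialect!r}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    df = df[cols].copy()
    df.columns = _NATIVE_COLS
    if dialect == "trackmate_export" and pixel_size is not None:
        df[["x_um", "y_um"]] *= pixel_size
    fi = frame_interval if frame_interval is not None else 1.0

    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy(int)
        if len(frames) >= 2 and not np.all(np.diff(frames) > 0):
            raise ValueError(f"{path.name}: non-monotone frames in track {tid}")
        tracks.append(Track(tid, frames, grp[["x_um", "y_um"]].to_numpy(float), fi))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    path = Path(path)
    fi = tracks[0].frame_interval if tracks else 1.0
    rows = [
        {"track_id": t.track_id, "frame": int(f), "x_um": p[0], "y_um": p[1]}
        for t in tracks
        for f, p in zip(t.frames, t.positions)
    ]
    with open(path, "w") as fh:
        fh.write(f"# frame_interval_s = {fi}\n")
        # %.17g is round-trip exact for float64, keeping write(read(f)) == f
        pd.DataFrame(rows, columns=_NATIVE_COLS).to_csv(fh, index=False, float_format="%.17g")


def fit_eligible_tracks(tracks: list[Track]) -> list[Track]:
    """Drop tracks shorter than the five-frame linking minimum, with a warning."""
    kept = []
    for t in tracks:
        if t.fit_eligible:
            kept.append(t)
        else:
            log.warning("track %s has %d < %d frames; excluded from fitting",
                        t.track_id, t.n_frames, MIN_FIT_FRAMES)
    return kept


def read_contours(path, pixel_size: float = 0.065) -> dict[str, CellContour]:
    """Read contours from native CSV or a JSON file of per-cell vertex arrays."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {str(k): CellContour(np.asarray(v, float), pixel_size) for k, v in data.items()}
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ["cell_id", "vertex_index", "x_um", "y_um"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    out = {}
    for cid, grp in df.sort_values(["cell_id", "vertex_index"]).groupby("cell_id", sort=True):
        out[str(cid)] = CellContour(grp[["x_um", "y_um"]].to_numpy(float), pixel_size)
    return out


def write_contours(contours: dict[str, CellContour], path) -> None:
    rows = [
        {"cell_id": cid, "vertex_index": i, "x_um": v[0], "y_um": v[1]}
        for cid, c in contours.items()
        for i, v in enumerate(c.vertices)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


CONFIG_KEYS = {
    "tracks_path", "contours_path", "output_dir", "seed", "log_level",
    "frame_interval_s", "pixel_size_um", "trajectory", "contour",
    "filters", "mechanics",
}


def load_config(path) -> dict:
    """Load a run config; unknown top-level keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a key-value mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return cfg


def write_resolved_config(cfg: dict, output_dir) -> Path:
    """Write the fully resolved config next to the run outputs."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "resolved_config.yaml"
    target.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return target
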