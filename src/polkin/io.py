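"""File I/O: trajectory tables, TIFF stacks, run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .trajectories import REQUIRED_COLUMNS, TrajectorySet

logger = logging.getLogger("polkin")

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_stack",
    "write_stack",
    "write_manifest",
]


def read_trajectories(
    path,
    pixel_size: float = 0.108,
    frame_interval: float = 0.0125433,
    coords: str = "px",
    leading_frame_cutoff: int = 0,
    nucleus_mask: Optional[np.ndarray] = None,
    sep: str = ",",
) -> TrajectorySet:
    """Read a delimited trajectory table (trajectory, frame, x, y).

    ``coords='px'`` converts pixel coordinates to μm with
    ``pixel_size``; ``'um'`` takes them as physical already.  The
    leading-frame cutoff drops bleach-affected early frames (use 0 for
    synthetic data).  When a nuclear label mask (2D, matching the pixel
    grid) is supplied, only tracks whose mean position falls on a
    non-zero label are kept and the label is recorded per track.
    Tracks left with fewer than 2 points are dropped with a logged
    count.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in REQUIRED_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
    if coords == "px":
        df["x"] = df["x"] * pixel_size
        df["y"] = df["y"] * pixel_size
    elif coords != "um":
        raise ValueError("coords must be 'px' or 'um'")
    if leading_frame_cutoff:
        df = df[df["frame"] >= leading_frame_cutoff]
    if nucleus_mask is not None:
        mean = df.groupby("trajectory")[["x", "y"]].mean()
        col = np.clip((mean["x"] / pixel_size).round().astype(int), 0, nucleus_mask.shape[1] - 1)
        row = np.clip((mean["y"] / pixel_size).round().astype(int), 0, nucleus_mask.shape[0] - 1)
        lab = nucleus_mask[row.to_numpy(), col.to_numpy()]
        keep = mean.index[lab > 0]
        df = df[df["trajectory"].isin(keep)]
        df = df.merge(
            pd.Series(lab[lab > 0], index=keep, name="nucleus"),
            left_on="trajectory",
            right_index=True,
        )
    sizes = df.groupby("trajectory")["frame"].size()
    short = sizes.index[sizes < 2]
    if len(short):
        logger.info("dropping %d single-point tracks", len(short))
        df = df[~df["trajectory"].isin(short)]
    if df.empty:
        raise ValueError(f"{path}: no usable tracks after filtering")
    return TrajectorySet(
        df.reset_index(drop=True),
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )


def write_trajectories(ts: TrajectorySet, path) -> None:
    """Write the trajectory table as CSV (coordinates in μm)."""
    cols = [c for c in ("trajectory", "frame", "x", "y", "nucleus") if c in ts.tracks]
    ts.tracks[cols].to_csv(path, index=False)


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF; single pages come back with z = 1."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr


def write_stack(arr: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(arr))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, params: dict, seed, inputs=()) -> Path:
    """Record stage, parameters, seed and input digests for re-running."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
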