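"""Container for localized single-molecule trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("trajectory", "frame", "x", "y")


@dataclass
class TrajectorySet:
    """A set of 2D single-molecule tracks in physical units.

    Parameters
    ----------
    tracks : pandas.DataFrame
        One row per localization with columns ``trajectory`` (track id),
        ``frame`` (integer frame index), ``x``, ``y`` (μm).  An optional
        ``nucleus`` column associates each track with a nucleus id.
    frame_interval : float
        Time between consecutive frames, seconds.
    pixel_size : float
        Camera pixel size in μm (metadata only; coordinates are stored
        in μm).
    mask_id : optional
        Identifier of the nuclear mask the set was filtered with.

    Tracks with fewer than two points cannot contribute displacement
    statistics and are rejected at validation.
    """

    tracks: pd.DataFrame
    frame_interval: float
    pixel_size: float = 0.108
    mask_id: object = None
    _order: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.tracks.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.tracks = self.tracks.sort_values(["trajectory", "frame"]).reset_index(
            drop=True
        )
        sizes = self.tracks.groupby("trajectory", sort=True).size()
        if (sizes < 2).any():
            bad = sizes.index[sizes < 2].tolist()
            raise ValueError(f"tracks with <2 points: {bad[:5]} (n={len(bad)})")
        frames = self.tracks["frame"].to_numpy()
        ids = self.tracks["trajectory"].to_numpy()
        same = ids[1:] == ids[:-1]
        if np.any(same & (np.diff(frames) <= 0)):
            raise ValueError("frames must be strictly increasing within tracks")

    @property
    def n_tracks(self) -> int:
        return self.tracks["trajectory"].nunique()

    @property
    def track_ids(self) -> np.ndarray:
        return np.unique(self.tracks["trajectory"].to_numpy())

    def jumps(self) -> pd.DataFrame:
        """Per-jump displacements between consecutive localizations.

        Returns a frame with columns ``trajectory``, ``dx``, ``dy``,
        ``r`` (2D jump length, μm) and ``dt_frames`` (frame gap).  Only
        consecutive-frame jumps (gap 1) are retained.
        """
        t = self.tracks
        ids = t["trajectory"].to_numpy()
        same = ids[1:] == ids[:-1]
        dx = np.diff(t["x"].to_numpy())[same]
        dy = np.diff(t["y"].to_numpy())[same]
        gap = np.diff(t["frame"].to_numpy())[same]
        keep = gap == 1
        return pd.DataFrame(
            {
                "trajectory": ids[1:][same][keep],
                "dx": dx[keep],
                "dy": dy[keep],
                "r": np.hypot(dx[keep], dy[keep]),
                "dt_frames": gap[keep],
            }
        )

    def jump_sufficient_stats(self) -> pd.DataFrame:
        """Per-track jump count and sum of squared 2D displacements.

        These are the sufficient statistics of the Rayleigh jump
        likelihood used by the occupancy estimator.
        """
        j = self.jumps()
        j["r2"] = j["r"] ** 2
        g = j.groupby("trajectory", sort=True)
        return pd.DataFrame({"n_jumps": g.size(), "sum_r2": g["r2"].sum()})

    def mean_positions(self) -> pd.DataFrame:
        """Mean x/y per trajectory (μm), with nucleus id if present."""
        cols = {"x": "mean", "y": "mean"}
        g = self.tracks.groupby("trajectory", sort=True)
        out = g.agg(cols)
        if "nucleus" in self.tracks.columns:
            out["nucleus"] = g["nucleus"].first()
        return out

    def subset(self, track_ids) -> "TrajectorySet":
        keep = self.tracks["trajectory"].isin(np.asarray(track_ids))
        return TrajectorySet(
            self.tracks.loc[keep].copy(),
            frame_interval=self.frame_interval,
            pixel_size=self.pixel_size,
            mask_id=self.mask_id,
        )
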