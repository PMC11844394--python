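"""Directional persistence of trajectories: the fold-anisotropy metric.

For every interior point of a track, the angle between the incoming and
outgoing displacement vectors is computed (0° = forward, 180° = direct
reversal).  Fold anisotropy is the probability of a backward jump
(180° ± 30°) divided by the probability of a forward jump (0°–30°);
values above 1 indicate compact, re-visiting exploration.  Bound
trajectories are removed before angle computation because near-static
tracks produce noise-dominated angles, and jumps shorter than a
threshold (default 0.2 μm, calibrated on histone tracks) are excluded
for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import KineticBins
from .trajectories import TrajectorySet

__all__ = ["AnisotropyResult", "compute_jump_angles", "fold_anisotropy"]


@dataclass
class AnisotropyResult:
    fold: float
    n_angles: int
    bootstrap_sd: float
    infinite: bool = False


def compute_jump_angles(
    trajs: TrajectorySet,
    min_jump: float = 0.2,
    exclude_bound: bool = True,
    bins: Optional[KineticBins] = None,
    dcs: Optional[pd.Series] = None,
) -> np.ndarray:
    """Angles (degrees, [0, 180]) between successive displacements.

    Pairs in which either displacement is shorter than ``min_jump`` are
    dropped.  With ``exclude_bound`` (requires ``bins`` and per-track
    ``dcs``), trajectories whose DC falls in the lowest kinetic bin are
    removed first.
    """
    if exclude_bound:
        if bins is None or dcs is None:
            raise ValueError("exclude_bound requires bins and per-track DCs")
        if bins.boundaries.size == 0:
            raise ValueError("bins define no bound state")
        keep = dcs.index[dcs.to_numpy() > bins.boundaries[0]]
        trajs = trajs.subset(keep)

    t = trajs.tracks
    ids = t["trajectory"].to_numpy()
    xy = t[["x", "y"]].to_numpy()
    same = ids[1:] == ids[:-1]
    d = np.diff(xy, axis=0)
    # consecutive displacement pairs within the same track
    pair = same[1:] & same[:-1]
    v1 = d[:-1][pair]
    v2 = d[1:][pair]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 >= min_jump) & (n2 >= min_jump)
    if not ok.any():
        raise ValueError("no displacement pairs above the jump threshold")
    cosang = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def fold_anisotropy(
    angles: np.ndarray,
    half_window: float = 30.0,
    bootstrap: tuple = (0.5, 20, 0),
    min_angles: int = 100,
) -> AnisotropyResult:
    """Backward/forward jump-probability ratio.

    ``fold = P(angle in [180-w, 180]) / P(angle in [0, w])`` with
    window half-width ``w`` (endpoints inclusive).  The SD comes from
    recomputing the ratio on 20 random half-subsamples.  A zero forward
    count flags the result as infinite.
    """
    angles = np.asarray(angles, float)
    if angles.size < min_angles:
        raise ValueError(
            f"{angles.size} angles below the minimum of {min_angles}"
        )

    def ratio(a):
        back = np.count_nonzero(a >= 180.0 - half_window)
        fwd = np.count_nonzero(a <= half_window)
        if fwd == 0:
            return np.inf
        return back / fwd

    fold = ratio(angles)
    frac, reps, seed = bootstrap
    rng = np.random.default_rng(seed)
    k = max(1, int(round(frac * angles.size)))
    vals = []
    for _ in range(int(reps)):
        sub = rng.choice(angles, size=k, replace=False)
        vals.append(ratio(sub))
    vals = np.asarray(vals)
    finite = np.isfinite(vals)
    sd = float(np.std(vals[finite])) if finite.any() else np.nan
    return AnisotropyResult(
        fold=float(fold) if np.isfinite(fold) else np.inf,
        n_angles=int(angles.size),
        bootstrap_sd=sd,
        infinite=not np.isfinite(fold),
    )
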