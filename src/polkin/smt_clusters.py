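"""Clusters of single-molecule trajectories and matched control spots.

Trajectory mean positions are clustered per nucleus with DBSCAN
(eps = 0.2 μm, min_samples = 15), mirroring how RNAPII accumulations
are identified in tracking data.  Clusters larger than the HLB scale or
with low member density are filtered out.  For every cluster, matched
control spots of the same radius are rejection-sampled inside the
nucleus, away from all clusters and from each other, providing a
geometric null for inside-cluster kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .anisotropy import AnisotropyResult, compute_jump_angles, fold_anisotropy
from .kinetics import FractionTriple, KineticBins, compute_fractions
from .trajectories import TrajectorySet

__all__ = [
    "ClusterROI",
    "ControlSpot",
    "RegionKinetics",
    "cluster_trajectories",
    "elbow_scan",
    "place_control_spots",
    "region_kinetics",
]


@dataclass
class ClusterROI:
    member_ids: np.ndarray
    centroid: np.ndarray  # (x, y) μm
    radius: float  # effective radius, μm
    nucleus: object = None

    @property
    def n_members(self) -> int:
        return self.member_ids.size


@dataclass
class ControlSpot:
    center: np.ndarray  # (x, y) μm
    radius: float
    nucleus: object = None


@dataclass
class RegionKinetics:
    fractions: Optional[FractionTriple]
    anisotropy: Optional[AnisotropyResult]
    n_tracks: int
    flag: Optional[str] = None


def _local_density_counts(pos: np.ndarray, eps: float) -> np.ndarray:
    nn = NearestNeighbors(radius=eps).fit(pos)
    return np.array([len(ix) for ix in nn.radius_neighbors(pos, return_distance=False)])


def cluster_trajectories(
    trajs: TrajectorySet,
    eps: float = 0.2,
    min_samples: int = 15,
    max_radius: float = 0.5,
    density_percentile: Optional[float] = 75.0,
) -> list[ClusterROI]:
    """DBSCAN clusters of trajectory mean positions, per nucleus.

    ``eps`` is the maximum neighbor distance (0.2 μm) and
    ``min_samples`` the minimum cluster size (15), the elbow-validated
    defaults.  Clusters with effective radius above ``max_radius``
    (HLB scale) or whose members' mean local density falls below the
    nucleus-wide ``density_percentile`` of per-point local density are
    discarded; pass ``density_percentile=None`` to skip that filter.
    Effective radius is the RMS member distance to the centroid × √2.
    """
    mp = trajs.mean_positions()
    groups = (
        mp.groupby("nucleus") if "nucleus" in mp.columns else [(None, mp)]
    )
    out: list[ClusterROI] = []
    for nuc, sub in groups:
        pos = sub[["x", "y"]].to_numpy()
        if len(pos) < min_samples:
            continue
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pos)
        if density_percentile is not None:
            counts = _local_density_counts(pos, eps)
            density_cut = np.percentile(counts, density_percentile)
        for lab in np.unique(labels[labels >= 0]):
            m = labels == lab
            centroid = pos[m].mean(axis=0)
            rms = np.sqrt(np.mean(np.sum((pos[m] - centroid) ** 2, axis=1)))
            radius = rms * np.sqrt(2.0)
            if radius > max_radius:
                continue
            if density_percentile is not None and counts[m].mean() < density_cut:
                continue
            out.append(
                ClusterROI(
                    member_ids=sub.index.to_numpy()[m],
                    centroid=centroid,
                    radius=float(radius),
                    nucleus=nuc,
                )
            )
    return out


def elbow_scan(
    positions: np.ndarray, eps_range: Sequence[float], min_samples: int = 15
) -> pd.DataFrame:
    """Cluster count as a function of DBSCAN eps (elbow diagnostic)."""
    eps_range = np.asarray(eps_range, float)
    if eps_range.size == 0:
        raise ValueError("empty eps range")
    pos = np.asarray(positions, float)
    if len(pos) < min_samples:
        raise ValueError("need at least min_samples positions")
    rows = []
    for eps in eps_range:
        labels = DBSCAN(eps=float(eps), min_samples=min_samples).fit_predict(pos)
        rows.append({"eps": float(eps), "n_clusters": int(labels.max() + 1)})
    df = pd.DataFrame(rows)
    df["delta"] = df["n_clusters"].diff()
    return df


def place_control_spots(
    clusters: Sequence[ClusterROI],
    nucleus_geometry: dict,
    n_per_cluster: int = 30,
    seed: int = 0,
    max_attempts: int = 20000,
) -> list[ControlSpot]:
    """Rejection-sample matched control spots.

    ``nucleus_geometry`` maps nucleus id → ``(center_xy, radius)`` of
    the (disc) nuclear mask.  Each spot must (i) not overlap any
    cluster, (ii) not overlap other spots, (iii) have the radius of its
    matched cluster and (iv) lie fully inside the nucleus.
    """
    rng = np.random.default_rng(seed)
    spots: list[ControlSpot] = []
    for cl in clusters:
        geom = nucleus_geometry[cl.nucleus] if cl.nucleus in nucleus_geometry else (
            nucleus_geometry[None]
        )
        ncenter, nradius = np.asarray(geom[0], float), float(geom[1])
        same_nuc = [c for c in clusters if c.nucleus == cl.nucleus]
        placed = 0
        attempts = 0
        while placed < n_per_cluster:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"control-spot placement infeasible in nucleus {cl.nucleus!r} "
                    f"({placed}/{n_per_cluster} placed)"
                )
            attempts += 1
            if nradius <= cl.radius:
                raise RuntimeError(
                    f"control-spot placement infeasible in nucleus {cl.nucleus!r}: "
                    "spot radius exceeds nucleus radius"
                )
            p = ncenter + _sample_disc_point(rng, nradius - cl.radius)
            if any(
                np.hypot(*(p - c.centroid)) < cl.radius + c.radius for c in same_nuc
            ):
                continue
            if any(
                s.nucleus == cl.nucleus
                and np.hypot(*(p - s.center)) < cl.radius + s.radius
                for s in spots
            ):
                continue
            spots.append(ControlSpot(center=p, radius=cl.radius, nucleus=cl.nucleus))
            placed += 1
    return spots


def _sample_disc_point(rng: np.random.Generator, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform())
    th = rng.uniform(0.0, 2 * np.pi)
    return np.array([r * np.cos(th), r * np.sin(th)])


def region_kinetics(
    trajs: TrajectorySet,
    dcs: pd.Series,
    bins: KineticBins,
    clusters: Sequence[ClusterROI],
    control_spots: Sequence[ControlSpot] = (),
    min_jump: float = 0.2,
    min_angles: int = 100,
    profile=None,
) -> dict:
    """Kinetic fractions and anisotropy inside clusters, control spots
    and the remaining nucleoplasm.

    Each trajectory is assigned to exactly one region class by its mean
    position (cluster membership wins over control spots).  Classes
    with no tracks are flagged rather than fatal; anisotropy is flagged
    when fewer than ``min_angles`` qualifying angles exist.

    Fractions are computed by binning the per-trajectory DCs.  When the
    ``OccupancyProfile`` is passed as ``profile``, the mean posterior
    occupancy mass of the class's tracks is used instead — this avoids
    the short-track classification bias of hard DC assignment and is
    preferable when the quantity of interest is a fraction ratio.
    """
    mp = trajs.mean_positions()
    pos = mp[["x", "y"]].to_numpy()
    nuc = mp["nucleus"].to_numpy() if "nucleus" in mp.columns else np.full(len(mp), None)

    inside = np.zeros(len(mp), bool)
    for cl in clusters:
        m = (nuc == cl.nucleus) if cl.nucleus is not None else np.ones(len(mp), bool)
        d = np.hypot(pos[:, 0] - cl.centroid[0], pos[:, 1] - cl.centroid[1])
        inside |= m & (d <= cl.radius)
    in_spot = np.zeros(len(mp), bool)
    for sp in control_spots:
        m = (nuc == sp.nucleus) if sp.nucleus is not None else np.ones(len(mp), bool)
        d = np.hypot(pos[:, 0] - sp.center[0], pos[:, 1] - sp.center[1])
        in_spot |= m & (d <= sp.radius)
    in_spot &= ~inside
    outside = ~(inside | in_spot)

    out = {}
    for name, mask in (
        ("inside", inside),
        ("control", in_spot),
        ("outside", outside),
    ):
        ids = mp.index.to_numpy()[mask]
        if ids.size == 0:
            out[name] = RegionKinetics(None, None, 0, flag="empty region class")
            continue
        if profile is not None:
            from .kinetics import occupancy_fractions

            frac = occupancy_fractions(profile, bins, fov_id=name, track_ids=ids)
        else:
            frac = compute_fractions(dcs.loc[ids].to_numpy(), bins, fov_id=name)
        aniso = None
        flag = None
        try:
            angles = compute_jump_angles(
                trajs.subset(ids), min_jump=min_jump, exclude_bound=True,
                bins=bins, dcs=dcs.loc[ids],
            )
            aniso = fold_anisotropy(angles, min_angles=min_angles)
        except ValueError as exc:
            flag = f"anisotropy unavailable: {exc}"
        out[name] = RegionKinetics(frac, aniso, int(ids.size), flag=flag)
    return out
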