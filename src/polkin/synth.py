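"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline can be exercised on data produced
here: multi-state Brownian trajectory sets with localization noise and
optional dense "cluster" regions of elevated bound occupancy, volumetric
nuclei containing Gaussian-profile clusters and up to two persistent
brighter HLB-like foci, and Gaussian-mixture lifetime samples.

Trajectories are anchored at their mean position: increments are drawn
first and the whole track is then translated so that its empirical mean
equals a sampled anchor point.  Translation leaves every displacement
unchanged, while making region membership by mean position (the
convention used for cluster kinetics) exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trajectories import TrajectorySet

__all__ = [
    "SmtGenConfig",
    "VolGenConfig",
    "ClusterRegion",
    "GroundTruth",
    "gen_smt_dataset",
    "gen_volumetric_movie",
    "gen_lifetime_sample",
]


@dataclass(frozen=True)
class ClusterRegion:
    """Circular accumulation region inside a nucleus.

    ``bound_occupancy`` overrides the bound-state probability for tracks
    anchored inside the region (intermediate/fast keep their relative
    proportions).  ``density_factor`` multiplies the local density of
    trajectory anchors relative to the nucleoplasmic background, so that
    regions are recoverable by density-based clustering, as RNAPII
    accumulations are in tracking data.
    """

    center: tuple  # (x, y) μm, relative to nucleus center
    radius: float  # μm
    bound_occupancy: Optional[float] = None
    density_factor: float = 1.0


@dataclass
class SmtGenConfig:
    """Parameters of the multi-state Brownian trajectory generator.

    The three diffusive states emulate chromatin-bound, intermediate and
    freely diffusing RNAPII populations.  ``loc_error_sd`` is the static
    localization error per coordinate per frame (μm); the imaging
    default of 0.030 μm matches typical fast-tracking experiments.
    """

    n_trajectories: int = 1000
    frame_interval: float = 0.0125433  # s (12.5433 ms)
    state_occupancies: Sequence[float] = (0.37, 0.27, 0.36)
    state_dc: Sequence[float] = (0.01, 1.0, 10.0)  # μm²/s
    loc_error_sd: float = 0.030  # μm
    mean_track_len: float = 8.0  # frames
    nucleus_diameter: float = 8.0  # μm
    cluster_regions: Optional[Sequence[ClusterRegion]] = None
    n_nuclei: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.state_occupancies, float)
        if self.n_trajectories <= 0:
            raise ValueError("n_trajectories must be positive")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("state_occupancies must sum to 1")
        if np.any(occ < 0):
            raise ValueError("state_occupancies must be non-negative")
        dc = np.asarray(self.state_dc, float)
        if len(dc) != len(occ):
            raise ValueError("state_dc and state_occupancies length mismatch")
        if np.any(np.diff(dc) <= 0):
            raise ValueError("state_dc must be strictly increasing")
        if self.loc_error_sd < 0:
            raise ValueError("loc_error_sd must be >= 0")
        if self.mean_track_len < 2:
            raise ValueError("mean_track_len must be >= 2 frames")


@dataclass
class VolGenConfig:
    """Parameters of the volumetric nucleus movie generator.

    A spherical nucleus of baseline intensity 1.0 contains transient 3D
    Gaussian clusters whose peak intensity is ``cluster_enrichment``
    fold over the nuclear mean, plus up to two brighter, larger
    HLB-like foci that persist for the whole movie.  Cluster lifetimes
    are drawn from a two-component Gaussian mixture (minutes).
    """

    nucleus_radius: float = 2.5  # μm
    n_clusters: int = 8
    cluster_enrichment: float = 2.0  # peak fold over nuclear mean
    cluster_sigma: float = 0.2  # μm
    n_hlbs: int = 2
    hlb_enrichment: float = 5.0
    hlb_sigma_factor: float = 1.5  # HLB sigma relative to cluster sigma
    min_separation: float = 1.2  # μm between planted structure centers
    lifetime_mixture: tuple = ((0.67, 0.33), (2.0, 7.0), (1.0, 2.0))
    frame_interval_s: float = 10.0
    n_frames: int = 60
    noise_sd: float = 0.0
    voxel_size: tuple = (0.3, 0.108, 0.108)  # (z, y, x) μm
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_hlbs <= 2:
            raise ValueError("n_hlbs must be 0, 1 or 2")
        if self.n_clusters > 0 and self.cluster_enrichment <= 1:
            raise ValueError("cluster_enrichment must exceed 1")
        w = np.asarray(self.lifetime_mixture[0], float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("lifetime mixture weights must sum to 1")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")


@dataclass
class GroundTruth:
    """Generator-side truth accompanying a synthetic dataset."""

    state_labels: Optional[pd.Series] = None  # per-trajectory state index
    region_index: Optional[pd.Series] = None  # per-trajectory region (-1 = bg)
    anchors: Optional[pd.DataFrame] = None  # per-trajectory mean position
    cluster_centers: Optional[np.ndarray] = None  # (n, 3) z/y/x μm
    cluster_frames: Optional[np.ndarray] = None  # (n, 2) start/end frame
    cluster_lifetimes_min: Optional[np.ndarray] = None
    hlb_centers: Optional[np.ndarray] = None
    engaged_counts: Optional[np.ndarray] = None
    burst_windows: Optional[np.ndarray] = None


def _sample_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def gen_smt_dataset(cfg: SmtGenConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Generate a multi-state Brownian trajectory set.

    Each trajectory is assigned a single diffusive state for its whole
    life (per-coordinate increment variance ``2 D Δt``), localization
    noise of SD ``loc_error_sd`` is added independently per coordinate
    per frame, and track lengths are geometric with the configured mean
    (photobleaching proxy), truncated at 2 points.  Tracks are anchored
    at a mean position sampled uniformly in the nuclear disc (or, with
    elevated density, in cluster regions); positions that stray outside
    the nucleus are radially reflected back inside.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trajectories
    R = cfg.nucleus_diameter / 2.0
    occ = np.asarray(cfg.state_occupancies, float)
    dcs = np.asarray(cfg.state_dc, float)
    regions = list(cfg.cluster_regions or [])

    # nucleus assignment (nuclei are laid out on a coarse grid; regions
    # are replicated in every nucleus)
    nuc_of = rng.integers(0, cfg.n_nuclei, size=n)
    spacing = cfg.nucleus_diameter * 1.5
    nuc_centers = np.column_stack(
        [spacing * np.arange(cfg.n_nuclei), np.zeros(cfg.n_nuclei)]
    )

    # choose anchor region: background vs cluster regions, weighted by
    # area x density_factor
    area_bg = np.pi * R**2 - sum(np.pi * rg.radius**2 for rg in regions)
    weights = [area_bg] + [
        np.pi * rg.radius**2 * rg.density_factor for rg in regions
    ]
    weights = np.asarray(weights, float)
    weights /= weights.sum()
    region_idx = rng.choice(len(weights), size=n, p=weights) - 1  # -1 = bg

    anchors = np.empty((n, 2))
    bg = region_idx < 0
    # rejection-sample background anchors outside all regions
    n_bg = int(bg.sum())
    pts = _sample_disc(rng, n_bg, R)
    if regions:
        for _ in range(200):
            inside = np.zeros(len(pts), bool)
            for rg in regions:
                d = np.hypot(pts[:, 0] - rg.center[0], pts[:, 1] - rg.center[1])
                inside |= d <= rg.radius
            if not inside.any():
                break
            pts[inside] = _sample_disc(rng, int(inside.sum()), R)
    anchors[bg] = pts
    for k, rg in enumerate(regions):
        m = region_idx == k
        anchors[m] = np.asarray(rg.center) + _sample_disc(rng, int(m.sum()), rg.radius)

    # per-trajectory state
    states = rng.choice(len(occ), size=n, p=occ)
    for k, rg in enumerate(regions):
        if rg.bound_occupancy is None:
            continue
        m = region_idx == k
        p = occ.copy()
        rest = occ[1:].sum()
        p[0] = rg.bound_occupancy
        p[1:] = occ[1:] * (1 - rg.bound_occupancy) / rest if rest > 0 else 0.0
        states[m] = rng.choice(len(occ), size=int(m.sum()), p=p)

    lengths = np.maximum(rng.geometric(1.0 / cfg.mean_track_len, size=n), 2)

    rows_id, rows_frame, rows_x, rows_y, rows_nuc = [], [], [], [], []
    for i in range(n):
        L = int(lengths[i])
        sd_step = np.sqrt(2.0 * dcs[states[i]] * cfg.frame_interval)
        steps = rng.normal(0.0, sd_step, size=(L - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos += rng.normal(0.0, cfg.loc_error_sd, size=(L, 2))
        pos += anchors[i] - pos.mean(axis=0)
        # radial reflection keeps positions within the nuclear disc
        rr = np.hypot(pos[:, 0], pos[:, 1])
        out = rr > R
        if out.any():
            scale = (2 * R - rr[out]) / rr[out]
            pos[out] *= np.clip(scale, 0.0, None)[:, None]
        pos_abs = pos + nuc_centers[nuc_of[i]]
        rows_id.append(np.full(L, i))
        rows_frame.append(np.arange(L))
        rows_x.append(pos_abs[:, 0])
        rows_y.append(pos_abs[:, 1])
        rows_nuc.append(np.full(L, nuc_of[i]))

    tracks = pd.DataFrame(
        {
            "trajectory": np.concatenate(rows_id),
            "frame": np.concatenate(rows_frame),
            "x": np.concatenate(rows_x),
            "y": np.concatenate(rows_y),
            "nucleus": np.concatenate(rows_nuc),
        }
    )
    ts = TrajectorySet(tracks, frame_interval=cfg.frame_interval)
    truth = GroundTruth(
        state_labels=pd.Series(states, index=np.arange(n), name="state"),
        region_index=pd.Series(region_idx, index=np.arange(n), name="region"),
        anchors=pd.DataFrame(anchors, columns=["x", "y"]),
    )
    return ts, truth


def gen_lifetime_sample(
    weights: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` positive lifetimes (minutes) from a Gaussian mixture.

    Non-positive draws are rejected and resampled, so the returned
    sample is from the mixture truncated to (0, ∞).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    w = np.asarray(weights, float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    mu = np.asarray(means, float)
    sd = np.asarray(sds, float)
    if np.any(mu <= 0):
        raise ValueError("means must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(w), size=m, p=w)
        draws = rng.normal(mu[comp], sd[comp])
        good = draws > 0
        k = int(good.sum())
        out[filled : filled + k] = draws[good]
        filled += k
    return out


def _gaussian_blob(shape, center_vox, sigma_vox):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = (
        (zz - center_vox[0]) ** 2 / (2 * sigma_vox[0] ** 2)
        + (yy - center_vox[1]) ** 2 / (2 * sigma_vox[1] ** 2)
        + (xx - center_vox[2]) ** 2 / (2 * sigma_vox[2] ** 2)
    )
    return np.exp(-q)


def gen_volumetric_movie(
    cfg: VolGenConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a volumetric nucleus movie with planted clusters.

    Returns ``(movie, nucleus_labels, truth)`` where ``movie`` has shape
    ``(t, z, y, x)``, baseline intensity 1 inside the spherical nucleus
    and 0 outside, and ``nucleus_labels`` is the matching integer label
    mask (single nucleus, label 1).  Clusters appear and disappear
    according to lifetimes drawn from the configured mixture; HLB-like
    foci persist through all frames.  Images emulate deconvolved data:
    ideal Gaussian profiles plus optional additive Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed)
    vz, vy, vx = cfg.voxel_size
    R = cfg.nucleus_radius
    margin = 3
    nz = int(np.ceil(2 * R / vz)) + 2 * margin
    ny = int(np.ceil(2 * R / vy)) + 2 * margin
    nx = int(np.ceil(2 * R / vx)) + 2 * margin
    center = np.array([nz / 2, ny / 2, nx / 2])

    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    dist2 = (
        ((zz - center[0]) * vz) ** 2
        + ((yy - center[1]) * vy) ** 2
        + ((xx - center[2]) * vx) ** 2
    )
    nucleus = dist2 <= R**2
    labels = nucleus.astype(np.int32)

    placed: list[np.ndarray] = []

    def sample_centers(k, interior_frac=0.65):
        # rejection sampling with a minimum pairwise separation so
        # planted structures stay individually resolvable
        pts = []
        attempts = 0
        while len(pts) < k:
            attempts += 1
            if attempts > 20000:
                raise ValueError(
                    "cannot place structures with the requested separation"
                )
            p = rng.uniform(-1, 1, size=3) * R * interior_frac
            if np.sum(p**2) > (R * interior_frac) ** 2:
                continue
            if any(
                np.linalg.norm(p - q) < cfg.min_separation for q in placed + pts
            ):
                continue
            pts.append(p)
        placed.extend(pts)
        return np.array(pts).reshape(k, 3)

    # planted clusters
    k = cfg.n_clusters
    centers = sample_centers(k) if k else np.empty((0, 3))
    w, mu, sd = cfg.lifetime_mixture
    if k:
        lifetimes = gen_lifetime_sample(w, mu, sd, k, seed=int(rng.integers(2**31)))
        dur = np.maximum(1, np.round(lifetimes * 60.0 / cfg.frame_interval_s)).astype(int)
        starts = rng.integers(0, np.maximum(1, cfg.n_frames - dur + 1))
        ends = np.minimum(starts + dur - 1, cfg.n_frames - 1)
    else:
        lifetimes = np.empty(0)
        starts = ends = np.empty(0, int)

    hlb_centers = sample_centers(cfg.n_hlbs) if cfg.n_hlbs else np.empty((0, 3))

    sig_c = np.array([cfg.cluster_sigma / vz, cfg.cluster_sigma / vy, cfg.cluster_sigma / vx])
    sig_h = sig_c * cfg.hlb_sigma_factor

    base = np.zeros((nz, ny, nx), np.float32)
    base[nucleus] = 1.0
    movie = np.empty((cfg.n_frames, nz, ny, nx), np.float32)
    blobs = [
        (cfg.cluster_enrichment - 1.0)
        * _gaussian_blob((nz, ny, nx), center + c / [vz, vy, vx], sig_c)
        for c in centers
    ]
    hlb_blobs = [
        (cfg.hlb_enrichment - 1.0)
        * _gaussian_blob((nz, ny, nx), center + c / [vz, vy, vx], sig_h)
        for c in hlb_centers
    ]
    for t in range(cfg.n_frames):
        frame = base.copy()
        for i, blob in enumerate(blobs):
            if starts[i] <= t <= ends[i]:
                frame += blob.astype(np.float32)
        for blob in hlb_blobs:
            frame += blob.astype(np.float32)
        frame[~nucleus] = 0.0
        if cfg.noise_sd > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sd, frame.shape).astype(np.float32)
        movie[t] = frame

    realized_min = (
        (ends - starts + 1) * cfg.frame_interval_s / 60.0 if k else np.empty(0)
    )
    centers_um = centers + center * [vz, vy, vx] if k else centers
    hlb_um = (
        hlb_centers + center * [vz, vy, vx] if cfg.n_hlbs else hlb_centers
    )
    truth = GroundTruth(
        cluster_centers=centers_um,
        cluster_frames=np.column_stack([starts, ends]) if k else np.empty((0, 2), int),
        cluster_lifetimes_min=realized_min,
        hlb_centers=hlb_um,
    )
    return movie, labels, truth
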