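"""Diffusion-state kinetics from single-molecule trajectories.

The estimator fits a fixed-grid mixture model to the 2D jump lengths of
all trajectories: a grid of 100 log-spaced diffusion coefficients D
(0.001–100 μm²/s) defines Rayleigh jump-length components with
per-coordinate variance ``2 D Δt + 2 σ²`` (σ = static localization
error), and the mixing weights over the grid — the state occupancies —
are obtained by EM.  Because the log-likelihood is concave in the
mixing weights, EM converges to the global maximum-likelihood
occupancy.  Each trajectory keeps its posterior responsibility vector
over the grid, from which a single diffusion coefficient is assigned as
the weighted geometric mean.

Kinetic states (bound / intermediate / fast) are delimited by local
minima of the smoothed occupancy profile; the chromatin-bound fraction
under transcription inhibitors can then be decomposed by subtraction
into non-specific, initiating and elongating components, and fraction
compositions are compared across conditions via the centered log-ratio
transform with Mann–Whitney U tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu

from .trajectories import TrajectorySet

__all__ = [
    "OccupancyProfile",
    "KineticBins",
    "FractionTriple",
    "BoundDecomposition",
    "default_dc_grid",
    "estimate_occupancy",
    "detect_state_boundaries",
    "assign_trajectory_dc",
    "compute_fractions",
    "occupancy_fractions",
    "estimate_localization_error",
    "decompose_bound",
    "elongating_fold_change",
    "clr_transform",
    "clr_and_test",
]

GRID_MIN = 1e-3  # μm²/s
GRID_MAX = 1e2  # μm²/s
GRID_POINTS = 100


def default_dc_grid(
    n: int = GRID_POINTS, lo: float = GRID_MIN, hi: float = GRID_MAX
) -> np.ndarray:
    """Log-spaced diffusion-coefficient grid, 0.001–100 μm²/s, 100 points."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class OccupancyProfile:
    """Occupancy over a diffusion-coefficient grid with per-track posteriors."""

    grid: np.ndarray  # (G,) μm²/s
    occupancy: np.ndarray  # (G,) sums to 1
    loc_error_sd: float  # μm
    per_track_weights: np.ndarray  # (n_tracks, G), rows sum to 1
    track_ids: np.ndarray  # (n_tracks,)
    log_likelihood: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.occupancy.sum() - 1.0) > 1e-6:
            raise ValueError("occupancy must sum to 1")
        row = self.per_track_weights.sum(axis=1)
        if self.per_track_weights.size and np.max(np.abs(row - 1.0)) > 1e-6:
            raise ValueError("per-track weights must sum to 1")


@dataclass
class KineticBins:
    """Diffusion-coefficient cut points delimiting kinetic states."""

    boundaries: np.ndarray  # (k,) μm²/s, strictly increasing
    labels: tuple = ()

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        self.boundaries = b
        if not self.labels:
            if b.size == 2:
                self.labels = ("bound", "intermediate", "fast")
            else:
                self.labels = tuple(f"state_{i}" for i in range(b.size + 1))

    @property
    def n_states(self) -> int:
        return self.boundaries.size + 1


@dataclass
class FractionTriple:
    """Bound / intermediate / fast fractions for one field of view."""

    bound: float
    intermediate: float
    fast: float
    n_tracks: int = 0
    fov_id: object = None
    bound_sd: Optional[float] = None

    def __post_init__(self) -> None:
        total = self.bound + self.intermediate + self.fast
        if min(self.bound, self.intermediate, self.fast) < 0:
            raise ValueError("fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.bound, self.intermediate, self.fast])


@dataclass
class BoundDecomposition:
    """Split of the vehicle bound fraction into kinetic sub-populations."""

    nonspecific: float
    initiating: float
    elongating: float
    nonspecific_sd: float = np.nan
    initiating_sd: float = np.nan
    elongating_sd: float = np.nan


def estimate_occupancy(
    trajs: TrajectorySet,
    grid: Optional[np.ndarray] = None,
    loc_error_sd: float = 0.030,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> OccupancyProfile:
    """Fit grid-mixture state occupancies to the trajectory jump lengths.

    Each grid coefficient D contributes, for a 2D jump of length r, a
    Rayleigh density with per-coordinate variance ``2 D Δt + 2 σ²``;
    one state is assumed per trajectory, so a track's contribution is
    the product over its jumps.  EM maximizes the mixture likelihood in
    the occupancy vector and returns the per-trajectory posterior
    responsibilities as the per-track weights.
    """
    if loc_error_sd < 0:
        raise ValueError("loc_error_sd must be >= 0")
    if grid is None:
        grid = default_dc_grid()
    grid = np.asarray(grid, float)
    stats = trajs.jump_sufficient_stats()
    if len(stats) == 0 or stats["n_jumps"].sum() == 0:
        raise ValueError("no jumps in trajectory set")
    m = stats["n_jumps"].to_numpy(float)  # (N,)
    s = stats["sum_r2"].to_numpy(float)  # (N,)
    track_ids = stats.index.to_numpy()

    var = 2.0 * grid * trajs.frame_interval + 2.0 * loc_error_sd**2  # (G,)
    # per-track per-grid log-likelihood, dropping jump-only terms
    ll = -np.outer(m, np.log(var)) - np.outer(s, 1.0 / (2.0 * var))  # (N, G)
    rowmax = ll.max(axis=1, keepdims=True)
    lik = np.exp(ll - rowmax)  # (N, G), fixed across iterations

    pi = np.full(len(grid), 1.0 / len(grid))
    prev = -np.inf
    for _ in range(max_iter):
        weighted = lik * pi  # (N, G)
        norm = weighted.sum(axis=1)  # (N,)
        total = float(np.log(norm).sum() + rowmax.sum())
        resp = weighted / norm[:, None]
        pi = resp.mean(axis=0)
        pi = np.clip(pi, 1e-300, None)
        pi /= pi.sum()
        if abs(total - prev) < tol * (1.0 + abs(total)):
            break
        prev = total
    occupancy = pi / pi.sum()
    resp /= resp.sum(axis=1, keepdims=True)
    return OccupancyProfile(
        grid=grid,
        occupancy=occupancy,
        loc_error_sd=loc_error_sd,
        per_track_weights=resp,
        track_ids=track_ids,
        log_likelihood=total,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(yp, kernel, mode="valid")


def detect_state_boundaries(
    profile: OccupancyProfile,
    smooth_window: int = 5,
    prominence_frac: float = 0.01,
    max_states: int = 3,
) -> KineticBins:
    """Place state boundaries at local minima of the smoothed occupancy.

    ``k`` minima yield ``k+1`` states; a unimodal profile yields a
    single state spanning the whole grid.  When more minima are found
    than ``max_states - 1``, the most prominent ones are kept and a
    warning is raised.
    """
    y = _smooth(profile.occupancy, smooth_window)
    prominence = prominence_frac * float(y.max())
    idx, props = find_peaks(-y, prominence=prominence)
    if max_states is not None and len(idx) > max_states - 1:
        warnings.warn(
            f"{len(idx)} occupancy minima found; keeping the "
            f"{max_states - 1} most prominent",
            stacklevel=2,
        )
        order = np.argsort(props["prominences"])[::-1][: max_states - 1]
        idx = np.sort(idx[order])
    return KineticBins(boundaries=profile.grid[idx])


def assign_trajectory_dc(profile: OccupancyProfile) -> pd.Series:
    """Per-trajectory diffusion coefficient (μm²/s).

    The posterior-weighted geometric mean over the grid:
    ``DC_i = exp(Σ_g w_ig ln D_g)``.
    """
    w = profile.per_track_weights
    row = w.sum(axis=1)
    if w.size and np.max(np.abs(row - 1.0)) > 1e-6:
        raise ValueError("per-track weight vectors must be normalized")
    dc = np.exp(w @ np.log(profile.grid))
    return pd.Series(dc, index=profile.track_ids, name="dc")


def compute_fractions(
    dcs: Sequence[float], bins: KineticBins, fov_id=None
) -> FractionTriple:
    """Fraction of trajectories whose DC falls in each kinetic bin.

    A DC exactly at a boundary is assigned to the lower bin.
    """
    dc = np.asarray(dcs, float)
    if dc.size == 0:
        raise ValueError("empty DC list")
    if bins.n_states != 3:
        raise ValueError("compute_fractions expects three kinetic states")
    which = np.searchsorted(bins.boundaries, dc, side="left")
    counts = np.bincount(which, minlength=3)
    frac = counts / dc.size
    return FractionTriple(
        bound=frac[0],
        intermediate=frac[1],
        fast=frac[2],
        n_tracks=dc.size,
        fov_id=fov_id,
    )


def occupancy_fractions(
    profile: OccupancyProfile,
    bins: KineticBins,
    fov_id=None,
    track_ids=None,
) -> FractionTriple:
    """State fractions as occupancy mass within each kinetic bin.

    This is the estimator-level reading of the bound/intermediate/fast
    fractions: the mixture occupancy integrated over each bin (grid
    points exactly at a boundary count toward the lower bin).  Unlike
    hard per-trajectory DC binning, it inherits the consistency of the
    maximum-likelihood occupancy and carries no short-track
    classification bias.  With ``track_ids`` the occupancy is
    recomputed as the mean posterior weight of that subset (per-FOV
    fractions).
    """
    if bins.n_states != 3:
        raise ValueError("occupancy_fractions expects three kinetic states")
    if track_ids is not None:
        sel = np.isin(profile.track_ids, np.asarray(track_ids))
        if not sel.any():
            raise ValueError("no tracks in the requested subset")
        occ = profile.per_track_weights[sel].mean(axis=0)
        n = int(sel.sum())
    else:
        occ = profile.occupancy
        n = profile.per_track_weights.shape[0]
    which = np.searchsorted(bins.boundaries, profile.grid, side="left")
    frac = np.array([occ[which == k].sum() for k in range(3)])
    frac /= frac.sum()
    return FractionTriple(
        bound=frac[0],
        intermediate=frac[1],
        fast=frac[2],
        n_tracks=n,
        fov_id=fov_id,
    )


def estimate_localization_error(
    trajs: TrajectorySet,
    dcs: Optional[pd.Series] = None,
    slow_dc_quantile: float = 0.1,
    min_jumps: int = 50,
) -> float:
    """Estimate the static localization error σ (μm).

    Uses the mean consecutive 2D displacement of the slowest-DC subset
    of trajectories.  For a static emitter with per-coordinate noise SD
    σ, the jump length is Rayleigh with scale σ√2 and mean σ√π, so
    σ = mean displacement / √π.

    When per-track DCs are supplied, the slow subset is every track
    whose DC lies in the lowest decile of the log grid range
    (DC ≤ 0.001·(10⁵)^quantile, ≈0.0032 μm²/s by default); without DCs
    all tracks are used (appropriate for static-emitter data).
    """
    if dcs is not None:
        cutoff = GRID_MIN * (GRID_MAX / GRID_MIN) ** slow_dc_quantile
        slow_ids = dcs.index[dcs.to_numpy() <= cutoff]
        if len(slow_ids) == 0:
            raise ValueError("no trajectories in the slow-DC subset")
        trajs = trajs.subset(slow_ids)
    jumps = trajs.jumps()
    if len(jumps) < min_jumps:
        raise ValueError(
            f"only {len(jumps)} jumps available (minimum {min_jumps})"
        )
    return float(jumps["r"].mean() / np.sqrt(np.pi))


def _bound_of(x) -> tuple[float, float]:
    if isinstance(x, FractionTriple):
        return x.bound, (x.bound_sd if x.bound_sd is not None else 0.0)
    return float(x), 0.0


def decompose_bound(
    vehicle,
    triptolide_bound,
    amanitin_bound,
    vehicle_sd: float = 0.0,
    triptolide_sd: float = 0.0,
    amanitin_sd: float = 0.0,
) -> BoundDecomposition:
    """Subtraction decomposition of the vehicle bound fraction.

    The residual bound fraction under an initiation inhibitor
    (triptolide) is assigned to non-specific binding; the elongation
    inhibitor (α-amanitin) residual minus the triptolide residual gives
    the initiating component; the remainder up to the vehicle bound
    fraction is elongating.  SDs propagate as root-sum-squares under
    subtraction.  Inputs may be ``FractionTriple``s or bare fractions.
    """
    v, v_sd0 = _bound_of(vehicle)
    t, t_sd0 = _bound_of(triptolide_bound)
    a, a_sd0 = _bound_of(amanitin_bound)
    v_sd = vehicle_sd or v_sd0
    t_sd = triptolide_sd or t_sd0
    a_sd = amanitin_sd or a_sd0
    eps = 1e-12
    if not (-eps <= t <= a + eps and a <= v + eps):
        raise ValueError(
            "inconsistent inputs: need 0 <= triptolide <= amanitin <= vehicle "
            f"(got {t:.4f}, {a:.4f}, {v:.4f})"
        )
    return BoundDecomposition(
        nonspecific=t,
        initiating=max(a - t, 0.0),
        elongating=max(v - a, 0.0),
        nonspecific_sd=t_sd,
        initiating_sd=float(np.hypot(a_sd, t_sd)),
        elongating_sd=float(np.hypot(v_sd, a_sd)),
    )


def elongating_fold_change(
    d13: BoundDecomposition, d14: BoundDecomposition
) -> tuple[float, float]:
    """Ratio of elongating fractions between two cycles, with SD.

    SD follows relative-error propagation for a ratio.
    """
    if d13.elongating <= 0:
        raise ValueError("denominator elongating fraction must be positive")
    fold = d14.elongating / d13.elongating
    rel13 = (d13.elongating_sd or 0.0) / d13.elongating
    rel14 = (d14.elongating_sd or 0.0) / d14.elongating if d14.elongating else 0.0
    if np.isnan(rel13):
        rel13 = 0.0
    if np.isnan(rel14):
        rel14 = 0.0
    return fold, fold * float(np.hypot(rel13, rel14))


def clr_transform(fractions: np.ndarray, pseudo: Optional[np.ndarray] = None) -> np.ndarray:
    """Centered log-ratio transform of compositional rows.

    Zero components are multiplicatively replaced by ``pseudo`` (per
    row) before transforming; rows are renormalized so the composition
    still sums to 1.  CLR rows sum to 0 by construction.
    """
    f = np.array(fractions, float, copy=True)
    if f.ndim == 1:
        f = f[None, :]
    if pseudo is not None:
        pseudo = np.broadcast_to(np.asarray(pseudo, float), (f.shape[0],))
        for i in range(f.shape[0]):
            zero = f[i] == 0
            if zero.any():
                f[i, zero] = pseudo[i]
                f[i, ~zero] *= (1.0 - zero.sum() * pseudo[i]) / f[i, ~zero].sum()
    if np.any(f <= 0):
        raise ValueError("CLR requires strictly positive fractions")
    logf = np.log(f)
    return logf - logf.mean(axis=1, keepdims=True)


def clr_and_test(
    groupA: Sequence[FractionTriple],
    groupB: Sequence[FractionTriple],
) -> dict:
    """Compare two groups of per-FOV compositions on the CLR scale.

    Each field-of-view triple is CLR-transformed (zeros replaced by
    0.5/n_tracks) and each component is compared across groups with a
    two-sided Mann–Whitney U test.  Returns component-name → p-value.
    """
    if len(groupA) < 2 or len(groupB) < 2:
        raise ValueError("each group needs at least 2 fields of view")

    def prep(group):
        arr = np.array([g.as_array() for g in group])
        pseudo = np.array(
            [0.5 / g.n_tracks if g.n_tracks else 1e-6 for g in group]
        )
        return clr_transform(arr, pseudo=pseudo)

    a, b = prep(groupA), prep(groupB)
    labels = ("bound", "intermediate", "fast")
    out = {}
    for k, lab in enumerate(labels):
        out[lab] = float(mannwhitneyu(a[:, k], b[:, k], alternative="two-sided").pvalue)
    return out
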