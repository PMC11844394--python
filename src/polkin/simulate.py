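"""Stochastic RNAPII loading/elongation at an active gene, with rendering.

The model: while the promoter is ON (the first ``t_on`` minutes), one
loading attempt succeeds per 0.1 s step with probability ``k_on``.
Every engaged polymerase advances at ``r_elongation`` (2.5 kb/min) and
leaves the gene on completing its ``gene_length`` (2.8 kb) or, each
step, with dissociation probability ``k_off``.  With ``k_off = 0`` the
steady-state engaged count follows Little's law: arrival rate
``k_on/dt`` times the traversal time ``L/r``.

Rendering mimics a 3-slice max-projection of a lattice light-sheet
acquisition: engaged molecules occupy a 1 μm-diameter region around the
gene, a background population (the ~50,000 nuclear RNAPII molecules
scaled to a 0.9 μm projection of the 5 μm nucleus) fills the nuclear
disc, and every molecule is convolved with a Gaussian PSF of 400 nm
FWHM on a 0.108 μm pixel grid.  Traces are sub-sampled every 9 s to
match reporter imaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .bursts import BurstTrace, _moving_average, segment_bursts_and_metrics

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "simulate_gene",
    "render_frame",
    "simulated_locus_trace",
    "sweep_kon",
]


@dataclass
class SimConfig:
    """Gene-loading simulator parameters (defaults match nc14 imaging)."""

    k_on: float = 0.1  # loading probability per 0.1 s step
    k_off: float = 0.0  # dissociation probability per step
    r_elongation: float = 2.5  # kb/min
    gene_length: float = 2.8  # kb
    t_on: float = 15.0  # min promoter ON
    t_total: Optional[float] = None  # min; default t_on + 2 traversal times
    nucleus_diameter: float = 5.0  # μm
    molecule_diameter: float = 15.0  # nm
    gene_region_diameter: float = 1.0  # μm
    psf_fwhm: float = 400.0  # nm
    n_total_molecules: int = 50_000
    projection_thickness: float = 0.9  # μm (3 slices at 0.3 μm)
    dt: float = 0.1  # s
    sample_interval: float = 9.0  # s
    pixel_size: float = 0.108  # μm
    exclude_volume: bool = False  # block loading while the promoter footprint is occupied
    koff_pre_elongation_only: bool = False
    mcp_cassette_pos: float = 0.0  # kb; engaged molecules past this count toward MCP proxy
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.k_on, self.k_off):
            if not 0.0 <= p <= 1.0:
                raise ValueError("k_on and k_off must be probabilities in [0, 1]")
        for v in (
            self.r_elongation,
            self.gene_length,
            self.t_on,
            self.nucleus_diameter,
            self.gene_region_diameter,
            self.psf_fwhm,
            self.dt,
            self.sample_interval,
            self.pixel_size,
        ):
            if v <= 0:
                raise ValueError("lengths, rates and intervals must be positive")

    @property
    def traversal_time_s(self) -> float:
        return self.gene_length / self.r_elongation * 60.0

    @property
    def loading_rate_per_s(self) -> float:
        return self.k_on / self.dt

    @property
    def n_background(self) -> int:
        return int(
            round(
                self.n_total_molecules
                * self.projection_thickness
                / self.nucleus_diameter
            )
        )

    @classmethod
    def from_rates(cls, kon_per_s: float, koff_per_s: float = 0.0, **kwargs):
        """Alias accepting per-second rates instead of per-step probabilities."""
        dt = kwargs.get("dt", 0.1)
        return cls(k_on=kon_per_s * dt, k_off=koff_per_s * dt, **kwargs)


@dataclass
class SimState:
    """Engaged polymerase positions (kb along the gene) at one sample."""

    time: float  # s
    promoter_on: bool
    positions: np.ndarray  # kb


@dataclass
class SimResult:
    times: np.ndarray  # sampled times, s (9 s spacing)
    states: list  # SimState per sample
    engaged_counts: np.ndarray  # per sample
    mcp_proxy: np.ndarray  # per sample
    n_loaded: int
    n_completed: int
    n_dissociated: int

    @property
    def final_engaged(self) -> int:
        return int(self.engaged_counts[-1])


def simulate_gene(cfg: SimConfig) -> SimResult:
    """Run the discrete-time loading/elongation simulation."""
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt
    t_total = (
        cfg.t_total * 60.0
        if cfg.t_total is not None
        else cfg.t_on * 60.0 + 2.0 * cfg.traversal_time_s
    )
    n_steps = int(round(t_total / dt))
    step_kb = cfg.r_elongation / 60.0 * dt
    footprint_kb = cfg.molecule_diameter / 0.34 / 1000.0  # B-DNA ~0.34 nm/bp

    sample_every = max(1, int(round(cfg.sample_interval / dt)))
    positions = np.empty(0)
    states: list[SimState] = []
    counts, proxies, times = [], [], []
    n_loaded = n_completed = n_dissociated = 0

    for step in range(n_steps + 1):
        t = step * dt
        promoter_on = t < cfg.t_on * 60.0
        if step % sample_every == 0:
            states.append(
                SimState(time=t, promoter_on=promoter_on, positions=positions.copy())
            )
            counts.append(positions.size)
            proxies.append(int(np.count_nonzero(positions >= cfg.mcp_cassette_pos)))
            times.append(t)
        if step == n_steps:
            break
        # dissociation
        if cfg.k_off > 0 and positions.size:
            if cfg.koff_pre_elongation_only:
                at_risk = positions <= footprint_kb
            else:
                at_risk = np.ones(positions.size, bool)
            drop = at_risk & (rng.uniform(size=positions.size) < cfg.k_off)
            n_dissociated += int(drop.sum())
            positions = positions[~drop]
        # elongation and completion
        positions = positions + step_kb
        finished = positions >= cfg.gene_length
        n_completed += int(finished.sum())
        positions = positions[~finished]
        # loading
        if promoter_on and rng.uniform() < cfg.k_on:
            blocked = cfg.exclude_volume and np.any(positions < footprint_kb)
            if not blocked:
                positions = np.append(positions, 0.0)
                n_loaded += 1
    return SimResult(
        times=np.asarray(times),
        states=states,
        engaged_counts=np.asarray(counts),
        mcp_proxy=np.asarray(proxies, float),
        n_loaded=n_loaded,
        n_completed=n_completed,
        n_dissociated=n_dissociated,
    )


def _image_grid(cfg: SimConfig) -> int:
    return int(np.ceil(cfg.nucleus_diameter / cfg.pixel_size)) + 4


def render_frame(
    state: SimState, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Render one PSF-convolved frame (engaged molecules + background).

    Engaged molecules are placed uniformly in the 1 μm gene region at
    the nucleus center; ``n_background`` molecules are placed uniformly
    in the projected nuclear disc; everything is convolved with a
    Gaussian PSF of ``psf_fwhm`` (σ = FWHM/2.355).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    npix = _image_grid(cfg)
    center = npix / 2.0
    R_nuc_px = cfg.nucleus_diameter / 2.0 / cfg.pixel_size
    R_gene_px = cfg.gene_region_diameter / 2.0 / cfg.pixel_size

    def disc(n, radius):
        r = radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([center + r * np.cos(th), center + r * np.sin(th)])

    pts = [disc(cfg.n_background, R_nuc_px)]
    if state.positions.size:
        pts.append(disc(state.positions.size, R_gene_px))
    pts = np.vstack(pts)
    img, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=npix, range=[[0, npix], [0, npix]]
    )
    sigma_px = cfg.psf_fwhm / 2.355 / 1000.0 / cfg.pixel_size
    return ndi.gaussian_filter(img, sigma_px)


def _region_masks(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    npix = _image_grid(cfg)
    yy, xx = np.ogrid[:npix, :npix]
    c = npix / 2.0
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    gene = d2 <= (cfg.gene_region_diameter / 2.0 / cfg.pixel_size) ** 2
    nuc = d2 <= (cfg.nucleus_diameter / 2.0 / cfg.pixel_size) ** 2
    return gene, nuc


def simulated_locus_trace(
    frames: Sequence[np.ndarray], cfg: SimConfig, smooth_window: int = 3
) -> np.ndarray:
    """Mean enrichment of the gene region over the nuclear mean, per frame."""
    gene, nuc = _region_masks(cfg)
    out = np.empty(len(frames))
    for i, f in enumerate(frames):
        nuc_mean = f[nuc].mean()
        out[i] = f[gene].mean() / nuc_mean if nuc_mean > 0 else 0.0
    return _moving_average(out, smooth_window)


def simulate_and_trace(cfg: SimConfig) -> tuple[SimResult, np.ndarray]:
    """Simulate, render every sampled state, and return the enrichment trace."""
    res = simulate_gene(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    frames = [render_frame(s, cfg, rng) for s in res.states]
    return res, simulated_locus_trace(frames, cfg)


def sweep_kon(
    k_on_values: Sequence[float],
    reps: int = 3,
    cfg: Optional[SimConfig] = None,
    seed: int = 0,
    detect_enrichment: float = 1.65,
) -> pd.DataFrame:
    """Burst metrics and detectability as a function of k_on.

    For each (k_on, replicate): simulate, render, extract the RNAPII
    enrichment trace, segment bursts from the MCP-proxy trace
    (ground-truth engaged counts), and record loading rate, burst
    duration, max enrichment and whether the locus would pass the
    volumetric enrichment cutoff.
    """
    if len(k_on_values) == 0:
        raise ValueError("need at least one k_on value")
    base = cfg or SimConfig()
    rows = []
    for k_on in k_on_values:
        for rep in range(reps):
            c = SimConfig(
                **{
                    **base.__dict__,
                    "k_on": float(k_on),
                    "seed": seed + 1000 * rep,
                }
            )
            res, rnap = simulate_and_trace(c)
            trace = BurstTrace(
                times=res.times,
                mcp_intensity=_moving_average(res.mcp_proxy, 3),
                rnap_enrichment=rnap,
            )
            bursts = segment_bursts_and_metrics(trace)
            max_enr = float(rnap.max())
            rows.append(
                {
                    "k_on": float(k_on),
                    "rep": rep,
                    "loading_rate": bursts[0].loading_rate if bursts else np.nan,
                    "burst_duration": bursts[0].duration if bursts else np.nan,
                    "max_enrichment": max_enr,
                    "detectable": bool(max_enr >= detect_enrichment),
                    "n_bursts": len(bursts),
                }
            )
    return pd.DataFrame(rows)
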