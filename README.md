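# polkin

Quantitative tools for studying RNA Polymerase II (RNAPII) kinetics and
clustering during zygotic genome activation in early embryos.  The
package is aimed at labs doing fast single-molecule tracking (SMT) and
volumetric lattice light-sheet imaging of tagged RNAPII: it estimates
diffusion-state occupancies from trajectory tables, decomposes the
chromatin-bound fraction under transcription inhibitors, quantifies
trajectory anisotropy and density-based clustering, segments and tracks
nuclear RNAPII clusters in volumetric movies, extracts MS2/MCP
transcription-burst metrics, and simulates stochastic polymerase
loading at an active gene.  A synthetic-data module generates every
input with known ground truth, so the whole pipeline is testable
without imaging data.

## The model in brief

Each trajectory is a single-state 2D Brownian walk observed with static
localization error σ: a jump of length *r* has Rayleigh density with
per-coordinate variance `2 D Δt + 2 σ²`.  Occupancies over a fixed grid
of 100 log-spaced diffusion coefficients, D ∈ [10⁻³, 10²] μm²/s, are
fit by EM (the log-likelihood is concave in the mixing weights, so the
fit is the global MLE).  Local minima of the occupancy profile delimit
the bound / intermediate / fast states, and per-trajectory coefficients
are posterior-weighted geometric means `exp(Σ_g w_g ln D_g)`.

The bound fraction *B* measured under inhibitors decomposes by
subtraction: with triptolide (initiation blocked) the residual bound
fraction is non-specific; with α-amanitin (elongation stalled) the
residual adds the initiating molecules; so

    nonspecific = B_TRI
    initiating  = B_AMA − B_TRI
    elongating  = B_VEH − B_AMA

with root-sum-square error propagation.  Fold anisotropy is
P(backward jump, 180°±30°) / P(forward jump, 0°–30°) over consecutive
displacements above 0.2 μm.  Cluster lifetimes in volumetric movies are
modeled as a two-component Gaussian mixture (short- and long-lived
populations).  The gene simulator loads polymerases with per-0.1 s-step
probability k_on, elongates them at 2.5 kb/min along a 2.8 kb gene,
removes them at the end or with probability k_off per step, and renders
each molecule with a 400 nm-FWHM Gaussian PSF; with k_off = 0 the mean
engaged count obeys Little's law, (k_on/dt)·(L/r).

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

```python
import polkin
from polkin.kinetics import (estimate_occupancy, detect_state_boundaries,
                             occupancy_fractions, decompose_bound,
                             elongating_fold_change)

# 20,000 three-state trajectories at bound/intermediate/fast = 37/27/36 %
cfg = polkin.SmtGenConfig(n_trajectories=20000,
                          state_occupancies=(0.37, 0.27, 0.36), seed=101)
ts, truth = polkin.gen_smt_dataset(cfg)
prof = estimate_occupancy(ts, loc_error_sd=0.030)
bins = detect_state_boundaries(prof)
frac = occupancy_fractions(prof, bins)
print(f"bound fraction: {100*frac.bound:.1f} %  "
      f"(boundaries at {bins.boundaries[0]:.3f} and {bins.boundaries[1]:.2f} um^2/s)")

d13 = decompose_bound(0.37, 0.14, 0.37 / 1.7)   # vehicle, triptolide, amanitin
d14 = decompose_bound(0.51, 0.14, 0.51 / 2.3)
fold, sd = elongating_fold_change(d13, d14)
print(f"elongating fold change nc13 -> nc14: {fold:.2f}")
```

Output:

```
bound fraction: 37.4 %  (boundaries at 0.167 and 2.42 um^2/s)
elongating fold change nc13 -> nc14: 1.89
```

The recovered bound fraction matches the generator's 37 % setting to
well within one binomial standard error at n = 20,000, and the
subtraction decomposition of the measured vehicle/inhibitor fractions
shows the elongating population nearly doubling between the two nuclear
cycles.

A command-line interface mirrors the main stages:

```bash
polkin simulate-gene --kon 0.3 --koff 0.0 --t-on 15 --seed 1 --outdir sim_out
polkin run config.yaml        # any stage from a YAML config
```

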