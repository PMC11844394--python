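import warnings

import numpy as np
import pandas as pd
import pytest

from polkin.trajectories import TrajectorySet

warnings.filterwarnings("ignore", message=".*occupancy minima.*")


def make_tracks(rng, n_tracks, length, step_sd, origin_spread=0.0, start_id=0):
    """Random-walk tracks with Gaussian steps of per-coordinate SD step_sd."""
    rows = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, step_sd, size=(length - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos += rng.normal(0.0, origin_spread, size=2)
        rows.append(
            pd.DataFrame(
                {
                    "trajectory": start_id + i,
                    "frame": np.arange(length),
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def static_emitters():
    """1,000 static emitters, 100 frames, 30 nm localization noise."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(1000):
        pos = rng.normal(0.0, 0.030, size=(100, 2))
        rows.append(
            pd.DataFrame(
                {
                    "trajectory": i,
                    "frame": np.arange(100),
                    "x": pos[:, 0] + 2.0 * i,
                    "y": pos[:, 1],
                }
            )
        )
    return TrajectorySet(pd.concat(rows, ignore_index=True), frame_interval=0.0125433)


@pytest.fixture(scope="session")
def nc13_pipeline():
    """Shared 20,000-track three-state dataset at the nc13 occupancies,
    pushed through the occupancy/boundary pipeline."""
    import polkin
    from polkin.kinetics import (
        assign_trajectory_dc,
        detect_state_boundaries,
        estimate_occupancy,
    )

    cfg = polkin.SmtGenConfig(
        n_trajectories=20000, state_occupancies=(0.37, 0.27, 0.36), seed=101
    )
    ts, truth = polkin.gen_smt_dataset(cfg)
    prof = estimate_occupancy(ts, loc_error_sd=cfg.loc_error_sd)
    bins = detect_state_boundaries(prof)
    dcs = assign_trajectory_dc(prof)
    return {"cfg": cfg, "ts": ts, "truth": truth, "prof": prof, "bins": bins, "dcs": dcs}
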