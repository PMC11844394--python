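"""Occupancy estimation, state binning, decomposition and CLR statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polkin
from polkin.kinetics import (
    BoundDecomposition,
    FractionTriple,
    KineticBins,
    OccupancyProfile,
    assign_trajectory_dc,
    clr_and_test,
    clr_transform,
    compute_fractions,
    decompose_bound,
    default_dc_grid,
    detect_state_boundaries,
    elongating_fold_change,
    estimate_localization_error,
    estimate_occupancy,
    occupancy_fractions,
)


class TestEstimateOccupancy:
    def test_single_state_concentrates_on_true_dc(self):
        cfg = polkin.SmtGenConfig(
            n_trajectories=3000,
            state_occupancies=(0.0, 1.0, 0.0),
            state_dc=(0.01, 1.0, 10.0),
            loc_error_sd=0.0,
            seed=11,
        )
        ts, _ = polkin.gen_smt_dataset(cfg)
        prof = estimate_occupancy(ts, loc_error_sd=0.0)
        grid = prof.grid
        assert len(grid) == 100
        assert grid[0] == pytest.approx(1e-3) and grid[-1] == pytest.approx(1e2)
        near = np.abs(np.log(grid) - np.log(1.0)) <= np.diff(np.log(grid))[0] * 1.5
        assert prof.occupancy[near].sum() >= 0.90

    def test_two_state_mixture_split(self):
        cfg = polkin.SmtGenConfig(
            n_trajectories=10000,
            state_occupancies=(0.5, 0.0, 0.5),
            state_dc=(0.01, 1.0, 10.0),
            loc_error_sd=0.030,
            seed=12,
        )
        ts, _ = polkin.gen_smt_dataset(cfg)
        prof = estimate_occupancy(ts, loc_error_sd=0.030)
        # mass on each side of the inter-mode minimum (geometric midpoint)
        lo = prof.occupancy[prof.grid < np.sqrt(0.01 * 10.0)].sum()
        assert lo == pytest.approx(0.5, abs=0.05)

    def test_probability_vector_invariants(self):
        cfg = polkin.SmtGenConfig(n_trajectories=500, seed=13)
        ts, _ = polkin.gen_smt_dataset(cfg)
        prof = estimate_occupancy(ts, loc_error_sd=0.030)
        assert prof.occupancy.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(prof.per_track_weights.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_input_rejected(self):
        cfg = polkin.SmtGenConfig(n_trajectories=10, seed=1)
        ts, _ = polkin.gen_smt_dataset(cfg)
        with pytest.raises(ValueError):
            estimate_occupancy(ts, loc_error_sd=-0.1)


class TestBoundaries:
    @staticmethod
    def _profile(occupancy):
        grid = default_dc_grid()
        occupancy = occupancy / occupancy.sum()
        return OccupancyProfile(
            grid=grid,
            occupancy=occupancy,
            loc_error_sd=0.03,
            per_track_weights=np.empty((0, 100)),
            track_ids=np.empty(0, int),
        )

    def test_unimodal_gives_single_state(self):
        grid = default_dc_grid()
        occ = np.exp(-0.5 * ((np.log10(grid) - 0.0) / 0.4) ** 2)
        bins = detect_state_boundaries(self._profile(occ))
        assert bins.boundaries.size == 0
        assert bins.n_states == 1

    def test_trimodal_minima_match_direct_scan(self):
        grid = default_dc_grid()
        lg = np.log10(grid)
        occ = (
            np.exp(-0.5 * ((lg + 2) / 0.25) ** 2)
            + np.exp(-0.5 * ((lg - 0) / 0.25) ** 2)
            + np.exp(-0.5 * ((lg - 1) / 0.2) ** 2)
        )
        bins = detect_state_boundaries(self._profile(occ), smooth_window=1)
        assert bins.boundaries.size == 2
        # oracle: exhaustive local-minimum scan on the raw profile
        y = occ / occ.sum()
        minima = [
            grid[i]
            for i in range(1, 99)
            if y[i] < y[i - 1] and y[i] < y[i + 1]
        ]
        np.testing.assert_allclose(bins.boundaries, minima)
        # first minimum sits between the bound and intermediate modes
        assert 0.01 < bins.boundaries[0] < 1.0 < bins.boundaries[1] < 10.0

    def test_excess_minima_pruned_with_warning(self):
        grid = default_dc_grid()
        lg = np.log10(grid)
        occ = sum(
            np.exp(-0.5 * ((lg - c) / 0.15) ** 2) for c in (-2.5, -1, 0, 1, 2)
        )
        with pytest.warns(UserWarning):
            bins = detect_state_boundaries(self._profile(occ), smooth_window=1)
        assert bins.boundaries.size == 2


class TestTrajectoryDc:
    def _profile(self, weights):
        grid = default_dc_grid()
        return OccupancyProfile(
            grid=grid,
            occupancy=np.full(100, 0.01),
            loc_error_sd=0.03,
            per_track_weights=weights,
            track_ids=np.arange(weights.shape[0]),
        )

    def test_concentrated_weight_returns_grid_value(self):
        w = np.zeros((1, 100))
        w[0, 37] = 1.0
        prof = self._profile(w)
        assert assign_trajectory_dc(prof).iloc[0] == pytest.approx(prof.grid[37])

    def test_half_half_gives_geometric_mean(self):
        grid = default_dc_grid()
        i = int(np.argmin(np.abs(grid - 0.01)))
        j = int(np.argmin(np.abs(grid - 1.0)))
        w = np.zeros((1, 100))
        w[0, i] = w[0, j] = 0.5
        dc = assign_trajectory_dc(self._profile(w)).iloc[0]
        assert dc == pytest.approx(np.sqrt(grid[i] * grid[j]))

    def test_unnormalized_weights_rejected(self):
        w = np.full((2, 100), 0.02)
        with pytest.raises(ValueError):
            assign_trajectory_dc(self._profile(w))


class TestComputeFractions:
    BINS = KineticBins(boundaries=np.array([0.1, 3.0]))

    def test_all_bound(self):
        f = compute_fractions([0.01, 0.05, 0.002], self.BINS)
        assert (f.bound, f.intermediate, f.fast) == (1.0, 0.0, 0.0)
        assert f.n_tracks == 3

    def test_boundary_tie_goes_to_lower_bin(self):
        f = compute_fractions([0.1, 3.0, 50.0], self.BINS)
        assert f.bound == pytest.approx(1 / 3)
        assert f.intermediate == pytest.approx(1 / 3)
        assert f.fast == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_fractions([], self.BINS)

    def test_fraction_recovery_on_generator_truth(self, nc13_pipeline):
        p = nc13_pipeline
        f = compute_fractions(p["dcs"].to_numpy(), p["bins"])
        # hard per-track binning recovers the planted bound fraction to
        # a few points (the occupancy-mass route is tested separately)
        assert f.bound == pytest.approx(0.37, abs=0.03)
        assert f.n_tracks == 20000

    def test_occupancy_mass_fractions(self, nc13_pipeline):
        p = nc13_pipeline
        f = occupancy_fractions(p["prof"], p["bins"])
        se = np.sqrt(0.37 * 0.63 / 20000)
        assert abs(f.bound - 0.37) < 3 * se


class TestLocalizationError:
    def test_noiseless_static_tracks(self):
        rows = []
        for i in range(50):
            rows.append(
                pd.DataFrame(
                    {"trajectory": i, "frame": np.arange(20), "x": float(i), "y": 0.0}
                )
            )
        ts = polkin.TrajectorySet(pd.concat(rows, ignore_index=True), frame_interval=0.0125)
        assert estimate_localization_error(ts) == 0.0

    def test_rayleigh_closed_form(self, static_emitters):
        sigma = estimate_localization_error(static_emitters)
        assert sigma == pytest.approx(0.030, abs=0.002)
        # and the raw mean displacement is sigma * sqrt(pi) = 0.0532 um
        assert static_emitters.jumps()["r"].mean() == pytest.approx(0.0532, abs=0.002)

    def test_min_jump_guard(self, static_emitters):
        with pytest.raises(ValueError):
            estimate_localization_error(static_emitters, min_jumps=10**9)


class TestDecomposition:
    def test_printed_worked_example(self):
        d = decompose_bound(0.51, 0.14, 0.22)
        assert d.nonspecific == pytest.approx(0.14)
        assert d.initiating == pytest.approx(0.08)
        assert d.elongating == pytest.approx(0.29)

    def test_degenerate_equal_inputs(self):
        d = decompose_bound(0.3, 0.3, 0.3)
        assert d.initiating == 0.0 and d.elongating == 0.0
        d0 = decompose_bound(0.3, 0.0, 0.2)
        assert d0.nonspecific == 0.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            decompose_bound(0.3, 0.25, 0.2)

    def test_components_sum_to_vehicle_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t, a, v = np.sort(rng.uniform(0.05, 0.95, 3))
            d = decompose_bound(v, t, a)
            assert d.nonspecific + d.initiating + d.elongating == pytest.approx(
                v, abs=1e-12
            )

    def test_sd_propagation(self):
        d = decompose_bound(0.51, 0.14, 0.22, vehicle_sd=0.08, triptolide_sd=0.05,
                            amanitin_sd=0.04)
        assert d.nonspecific_sd == pytest.approx(0.05)
        assert d.initiating_sd == pytest.approx(np.hypot(0.04, 0.05))
        assert d.elongating_sd == pytest.approx(np.hypot(0.08, 0.04))


class TestFoldChange:
    def test_printed_inputs_give_about_1p9(self):
        # vehicle 37 % / 51 %; triptolide residual 14 %; elongation-
        # inhibitor decreases 1.7- and 2.3-fold
        d13 = decompose_bound(0.37, 0.14, 0.37 / 1.7)
        d14 = decompose_bound(0.51, 0.14, 0.51 / 2.3)
        fold, _ = elongating_fold_change(d13, d14)
        assert fold == pytest.approx(1.89, abs=0.02)
        assert abs(fold - 1.8) <= 0.5  # printed tolerance

    def test_identity_and_scaling(self):
        d = decompose_bound(0.5, 0.1, 0.2)
        assert elongating_fold_change(d, d)[0] == pytest.approx(1.0)
        d2 = BoundDecomposition(0.1, 0.1, 2 * d.elongating)
        assert elongating_fold_change(d, d2)[0] == pytest.approx(2.0)

    def test_zero_denominator(self):
        d0 = decompose_bound(0.2, 0.1, 0.2)
        with pytest.raises(ValueError):
            elongating_fold_change(d0, d0)


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        np.testing.assert_allclose(clr_transform([1 / 3, 1 / 3, 1 / 3]), 0.0, atol=1e-12)

    def test_worked_example(self):
        out = clr_transform([0.5, 0.3, 0.2])[0]
        np.testing.assert_allclose(out, [0.476, -0.035, -0.441], atol=1e-3)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 0.98), min_size=3, max_size=3).filter(
            lambda v: sum(v) > 0.1
        )
    )
    def test_clr_rows_sum_to_zero(self, raw):
        comp = np.asarray(raw) / np.sum(raw)
        assert clr_transform(comp).sum() == pytest.approx(0.0, abs=1e-9)

    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(5)
        def fov():
            f = rng.dirichlet([10, 8, 9])
            return FractionTriple(*f, n_tracks=500)
        pool = [fov() for _ in range(40)]
        p = clr_and_test(pool[:20], pool[20:])
        assert all(v > 0.05 for v in p.values())

    def test_zero_replacement(self):
        a = [FractionTriple(0.5, 0.5, 0.0, n_tracks=100) for _ in range(3)]
        b = [FractionTriple(0.4, 0.4, 0.2, n_tracks=100) for _ in range(3)]
        p = clr_and_test(a, b)
        assert set(p) == {"bound", "intermediate", "fast"}

    def test_group_size_guard(self):
        f = FractionTriple(0.4, 0.3, 0.3, n_tracks=10)
        with pytest.raises(ValueError):
            clr_and_test([f], [f, f])
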