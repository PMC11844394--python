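"""Volumetric segmentation, HLB removal, lifetimes, survival, mixtures."""

import numpy as np
import pytest

import polkin
from polkin.synth import _gaussian_blob, gen_lifetime_sample
from polkin.volumetric import (
    ClusterRecord,
    detect_and_remove_hlbs,
    filter_and_density,
    fit_lifetime_mixture,
    segment_clusters,
    survival_curve,
    track_cluster_lifetimes,
)


def single_frame(seed, n_clusters=5, n_hlbs=0, **kw):
    cfg = polkin.VolGenConfig(
        n_clusters=n_clusters, n_hlbs=n_hlbs, noise_sd=0.0, n_frames=1, seed=seed, **kw
    )
    movie, labels, truth = polkin.gen_volumetric_movie(cfg)
    return cfg, movie, labels, truth


class TestSegmentClusters:
    def test_uniform_nucleus_has_no_clusters(self):
        _, movie, labels, _ = single_frame(1, n_clusters=0)
        _, recs = segment_clusters(movie[0], labels)
        assert recs == []

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_count_and_centroids(self, seed):
        cfg, movie, labels, truth = single_frame(seed)
        _, recs = segment_clusters(movie[0], labels)
        assert len(recs) == 5
        found = np.array([r.centroid for r in recs])
        tol = np.linalg.norm(cfg.voxel_size)  # one voxel diagonal
        for c in truth.cluster_centers:
            assert np.min(np.linalg.norm(found - c, axis=1)) <= tol

    def test_watershed_splits_fused_pair(self):
        # two clusters close enough to fuse in the binary mask but with
        # distinct intensity maxima
        cfg, movie, labels, truth = single_frame(
        	9, n_clusters=2, min_separation=0.75
        )
        _, recs = segment_clusters(movie[0], labels)
        assert len(recs) == 2

    def test_empty_nucleus_label_rejected(self):
        _, movie, labels, _ = single_frame(1, n_clusters=0)
        with pytest.raises(ValueError):
            segment_clusters(movie[0], np.zeros_like(labels))

    def test_density_invariant_to_intensity_rescale(self):
        _, movie, labels, _ = single_frame(2, cluster_enrichment=4.0)
        _, recs1 = segment_clusters(movie[0], labels)
        _, recs2 = segment_clusters(movie[0] * 7.5, labels)
        k1, d1 = filter_and_density(recs1, nuclear_volume=65.0)
        k2, d2 = filter_and_density(recs2, nuclear_volume=65.0)
        assert len(k1) == len(k2) and d1 == pytest.approx(d2)


class TestHlbRemoval:
    def test_no_large_foci_no_hlbs(self):
        _, movie, labels, _ = single_frame(3, n_clusters=5, n_hlbs=0)
        _, recs = segment_clusters(movie[0], labels)
        hlbs, kept = detect_and_remove_hlbs(movie[0], recs, labels)
        assert hlbs == [] and len(kept) == len(recs)

    def test_two_planted_hlbs_removed_clusters_remain(self):
        _, movie, labels, truth = single_frame(0, n_clusters=5, n_hlbs=2)
        _, recs = segment_clusters(movie[0], labels)
        hlbs, kept = detect_and_remove_hlbs(movie[0], recs, labels)
        assert len(hlbs) == 2
        assert len(kept) == 5
        found = np.array([h["centroid"] for h in hlbs])
        for c in truth.hlb_centers:
            assert np.min(np.linalg.norm(found - c, axis=1)) < 0.5

    def test_at_most_two_brightest_retained(self):
        # hand-built volume with three HLB-scale foci
        _, movie, labels, _ = single_frame(4, n_clusters=0, n_hlbs=0)
        vol = movie[0].copy()
        shape = vol.shape
        centers = [(11, 20, 20), (11, 32, 20), (11, 26, 34)]
        amps = [4.0, 3.9, 3.5]
        for c, a in zip(centers, amps):
            vol += a * _gaussian_blob(shape, c, (1.2, 3.2, 3.2)).astype(np.float32)
        vol[labels == 0] = 0.0
        hlbs, _ = detect_and_remove_hlbs(vol, [], labels)
        assert len(hlbs) == 2
        found_y = sorted(h["centroid"][1] / 0.108 for h in hlbs)
        assert found_y == pytest.approx([20, 32], abs=2)  # two brightest

    def test_skip_flag(self):
        _, movie, labels, _ = single_frame(0, n_clusters=3, n_hlbs=2)
        _, recs = segment_clusters(movie[0], labels)
        hlbs, kept = detect_and_remove_hlbs(movie[0], recs, labels, skip=True)
        assert hlbs == [] and kept == recs


class TestFilterAndDensity:
    def _rec(self, enr):
        return ClusterRecord(1, 1, 0, np.zeros(3), 0.05, enr, enr, 10)

    def test_unenriched_all_dropped(self):
        kept, dens = filter_and_density([self._rec(1.0)] * 4, nuclear_volume=100.0)
        assert kept == [] and dens == 0.0

    def test_density_arithmetic(self):
        kept, dens = filter_and_density(
            [self._rec(2.0)] * 12, enrichment_cutoff=1.65, nuclear_volume=268.0
        )
        assert len(kept) == 12
        assert dens == pytest.approx(12 / 268.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            filter_and_density([], nuclear_volume=0.0)


class TestLifetimeTracking:
    def _rec(self, frame, z, y=2.0, x=2.0, nucleus=1):
        return ClusterRecord(0, nucleus, frame, np.array([z, y, x]), 0.05, 2.0, 2.0, 10)

    def test_full_movie_cluster_normalized_to_one(self):
        recs = [self._rec(f, 3.0) for f in range(20)]
        out = track_cluster_lifetimes(recs, frame_interval_s=10.0, n_frames=20)
        assert len(out) == 1
        assert out[0].normalized_lifetime == pytest.approx(1.0)

    def test_z_gate_terminates_track(self):
        recs = [self._rec(0, 3.0), self._rec(1, 4.2)]  # 1.2 um z jump
        out = track_cluster_lifetimes(recs, frame_interval_s=10.0, n_frames=2)
        assert len(out) == 2

    def test_within_gate_links(self):
        recs = [self._rec(0, 3.0), self._rec(1, 3.5)]  # 0.5 um z jump
        out = track_cluster_lifetimes(recs, frame_interval_s=10.0, n_frames=2)
        assert len(out) == 1
        assert out[0].lifetime_min == pytest.approx(20 / 60)

    def test_planted_lifetimes_recovered_exactly(self):
        cfg = polkin.VolGenConfig(
            n_clusters=6, n_hlbs=0, noise_sd=0.0, n_frames=30, seed=5
        )
        movie, labels, truth = polkin.gen_volumetric_movie(cfg)
        records = []
        for f in range(movie.shape[0]):
            _, recs = segment_clusters(movie[f], labels, frame=f)
            records.extend(recs)
        out = track_cluster_lifetimes(records, cfg.frame_interval_s, cfg.n_frames)
        assert sorted((r.start_frame, r.end_frame) for r in out) == sorted(
            map(tuple, truth.cluster_frames.tolist())
        )
        np.testing.assert_allclose(
            sorted(r.lifetime_min for r in out),
            sorted(truth.cluster_lifetimes_min),
        )


class TestSurvivalCurve:
    def test_single_lifetime_step(self):
        t, S = survival_curve([5.0])
        assert S[t < 5.0].min() == 1.0
        assert S[-1] == 0.0

    def test_equal_lifetimes_step_function(self):
        t, S = survival_curve([3.0] * 10)
        np.testing.assert_array_equal(t, [0.0, 3.0])
        np.testing.assert_array_equal(S, [1.0, 0.0])

    def test_matches_brute_force_ccdf(self):
        s = gen_lifetime_sample((0.6, 0.4), (2, 7), (1, 2), 300, seed=3)
        t, S = survival_curve(s)
        for ti, Si in zip(t, S):
            assert Si == pytest.approx(np.mean(s > ti))

    def test_monotone_nonincreasing_with_S0_one(self):
        s = gen_lifetime_sample((0.5, 0.5), (2, 9), (1, 3), 500, seed=4)
        t, S = survival_curve(s)
        assert S[0] == 1.0
        assert np.all(np.diff(S) <= 0)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            survival_curve([])
        with pytest.raises(ValueError):
            survival_curve([1.0, -2.0])


class TestLifetimeMixture:
    def test_nc14_style_recovery(self):
        s = gen_lifetime_sample((0.67, 0.33), (2.0, 7.0), (1.0, 2.0), 5000, seed=6)
        fit = fit_lifetime_mixture(s, seed=0)
        assert fit.long_lived_fraction == pytest.approx(0.33, abs=0.02)
        assert fit.means[1] == pytest.approx(7.0, abs=0.2)

    def test_inhibited_style_recovery(self):
        s = gen_lifetime_sample((0.59, 0.41), (3.0, 14.0), (1.0, 3.0), 5000, seed=7)
        fit = fit_lifetime_mixture(s, seed=0)
        assert fit.long_lived_fraction == pytest.approx(0.41, abs=0.03)
        assert fit.means[1] == pytest.approx(14.0, abs=0.4)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_across_seeds(self, seed):
        s = gen_lifetime_sample((0.67, 0.33), (2.0, 7.0), (1.0, 2.0), 5000, seed=seed)
        fit = fit_lifetime_mixture(s, seed=seed)
        # 3 SEs: weight SE ~ sqrt(w(1-w)/n) ~ 0.0066; mean SE ~ sd/sqrt(nw)
        assert abs(fit.long_lived_fraction - 0.33) < 3 * 0.0066 + 0.01
        assert abs(fit.means[1] - 7.0) < 3 * 2.0 / np.sqrt(5000 * 0.33) + 0.1

    def test_degenerate_falls_back_flagged(self):
        fit = fit_lifetime_mixture(np.full(50, 4.2))
        assert fit.degenerate
        assert fit.means[0] == pytest.approx(4.2)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime_mixture([1.0] * 5)
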