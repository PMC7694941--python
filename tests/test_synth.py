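"""Ground-truth generator, trace simulation, movie rendering, toy atlas."""

import numpy as np
import pytest
from scipy import stats

import spectramap as sm
from spectramap.synth import truth_manifest


class TestGroundTruth:
    def test_zero_responder_fraction(self):
        cfg = sm.SynthConfig(n_neurons=1000, responder_fraction=0.0, seed=1)
        truth = sm.simulate_ground_truth(cfg, sm.make_atlas((4, 128, 256)))
        assert len(truth) == 1000
        assert all(not n.response_set for n in truth)

    def test_responder_count_within_binomial_interval(self):
        cfg = sm.SynthConfig(n_neurons=10000, responder_fraction=0.02, seed=7)
        truth = sm.simulate_ground_truth(cfg, sm.make_atlas((20, 256, 512)))
        k = sum(bool(n.response_set) for n in truth)
        lo, hi = stats.binom.interval(0.99, 10000, 0.02)
        assert lo <= k <= hi

    def test_same_seed_identical_manifest(self):
        cfg = sm.SynthConfig(n_neurons=500, seed=3)
        atlas = sm.make_atlas((4, 128, 256))
        m1 = truth_manifest(sm.simulate_ground_truth(cfg, atlas))
        m2 = truth_manifest(sm.simulate_ground_truth(cfg, atlas))
        assert m1.equals(m2)

    def test_minimum_spacing_enforced_within_planes(self):
        cfg = sm.SynthConfig(n_neurons=800, seed=5)
        truth = sm.simulate_ground_truth(cfg, sm.make_atlas((4, 128, 256)))
        min_dist = cfg.min_spacing_diameters * 2 * cfg.nucleus_sigma_px
        by_plane = {}
        for n in truth:
            by_plane.setdefault(n.z, []).append(n.centroid)
        for pts in by_plane.values():
            pts = np.asarray(pts, float)
            d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            # centroids are rounded to integer pixels after the check
            assert np.sqrt(d2.min()) >= min_dist - np.sqrt(2)

    def test_impossible_density_rejected(self):
        cfg = sm.SynthConfig(n_neurons=5000, seed=1)
        with pytest.raises(ValueError, match="density"):
            sm.simulate_ground_truth(cfg, sm.make_atlas((1, 32, 32)))


class TestTraces:
    def test_noiseless_responder_recovers_amplitude(self, schedule, cirf_params):
        nrn = sm.GroundTruthNeuron(
            id=0, z=0, centroid=(20, 20), region="M",
            response_set=frozenset({"L1"}), amplitude={"L1": 1.0},
            baseline_F=1000.0,
        )
        cfg = sm.SynthConfig(noise_sd=0.0, drift_amplitude=0.0)
        tm = sm.simulate_traces([nrn], schedule, cirf_params, cfg)
        t = schedule.frame_times_s
        expected = 1000.0 * (
            1 + sum(sm.cirf(t - o, cirf_params) for o in schedule.onsets("L1"))
        )
        np.testing.assert_allclose(tm.F[0], expected)
        # and the dF/F0 pipeline recovers the unit peak
        F0 = sm.estimate_baseline(tm.F[0])
        dff = sm.compute_dff(tm.F[0], F0)
        assert dff.max() == pytest.approx(1.0, rel=0.05)

    def test_nonresponder_is_flat_baseline(self, schedule, cirf_params):
        nrn = sm.GroundTruthNeuron(id=0, z=0, centroid=(20, 20), region="M")
        cfg = sm.SynthConfig(noise_sd=0.0, drift_amplitude=0.0)
        tm = sm.simulate_traces([nrn], schedule, cirf_params, cfg)
        np.testing.assert_allclose(tm.F[0], nrn.baseline_F)

    def test_inhibited_neuron_dips_below_baseline(self, schedule, cirf_params):
        nrn = sm.GroundTruthNeuron(
            id=0, z=0, centroid=(20, 20), region="D", sign=-1,
            response_set=frozenset({"L2"}), amplitude={"L2": 0.5},
        )
        cfg = sm.SynthConfig(noise_sd=0.0, drift_amplitude=0.0)
        tm = sm.simulate_traces([nrn], schedule, cirf_params, cfg)
        onset = schedule.onsets("L2")[0]
        after = (schedule.frame_times_s > onset) & (
            schedule.frame_times_s < onset + 6
        )
        assert np.all(tm.F[0][after] < nrn.baseline_F)
        # frame clock samples the CIRF peak to within ~0.3%
        assert tm.F[0].min() == pytest.approx(nrn.baseline_F * 0.5, rel=0.01)

    def test_same_seed_identical_traces(self, schedule, cirf_params):
        cfg = sm.SynthConfig(n_neurons=50, seed=11)
        truth = sm.simulate_ground_truth(cfg, sm.make_atlas((2, 64, 128)))
        a = sm.simulate_traces(truth, schedule, cirf_params, cfg)
        b = sm.simulate_traces(truth, schedule, cirf_params, cfg)
        np.testing.assert_array_equal(a.F, b.F)


class TestAtlas:
    def test_six_exclusive_labels_cover_the_volume(self):
        vol = sm.make_atlas((4, 96, 200))
        labels = set(np.unique(vol)) - {0}
        assert labels == {1, 2, 3, 4, 5, 6}

    def test_deterministic(self):
        np.testing.assert_array_equal(
            sm.make_atlas((3, 64, 128), seed=1), sm.make_atlas((3, 64, 128), seed=2)
        )


class TestMovie:
    def test_empty_truth_gives_stationary_noise(self, schedule, cirf_params):
        cfg = sm.SynthConfig(n_neurons=0, background_F=100.0)
        tm = sm.simulate_traces(
            [], schedule, cirf_params, cfg, frame_times_s=schedule.frame_times_s
        )
        stacks = sm.render_movie([], tm, (32, 32), seed=0, config=cfg)
        frame_means = stacks[0].astype(float).mean(axis=(1, 2))
        assert frame_means.std() < 0.05 * frame_means.mean()
        assert frame_means.mean() == pytest.approx(100.0, rel=0.05)

    def test_single_neuron_blob_at_centroid(self, schedule, cirf_params):
        nrn = sm.GroundTruthNeuron(
            id=0, z=0, centroid=(30, 40), region="M", baseline_F=5000.0
        )
        cfg = sm.SynthConfig(noise_sd=0.0, drift_amplitude=0.0, background_F=10.0)
        tm = sm.simulate_traces([nrn], schedule, cirf_params, cfg)
        stacks = sm.render_movie([nrn], tm, (64, 80), seed=0, config=cfg)
        mip = sm.max_projection(stacks[0].astype(float))
        assert np.unravel_index(np.argmax(mip), mip.shape) == (30, 40)

    def test_bleed_through_elevates_flash_frames(self, schedule, cirf_params):
        from spectramap.selection import stimulus_frame_mask

        cfg = sm.SynthConfig(n_neurons=0, background_F=100.0)
        tm = sm.simulate_traces(
            [], schedule, cirf_params, cfg, frame_times_s=schedule.frame_times_s
        )
        stacks = sm.render_movie(
            [], tm, (48, 48), seed=1, config=cfg,
            schedule=schedule, bleed_through=5.0,
        )
        med = np.median(stacks[0].astype(float), axis=(1, 2))
        mask = stimulus_frame_mask(schedule)
        assert med[mask].min() > med[~mask].mean() + 3 * med[~mask].std()

    def test_movie_reproducible_under_seed(self, schedule, cirf_params):
        cfg = sm.SynthConfig(n_neurons=20, seed=2)
        truth = sm.simulate_ground_truth(cfg, sm.make_atlas((1, 64, 128)))
        tm = sm.simulate_traces(truth, schedule, cirf_params, cfg)
        a = sm.render_movie(truth, tm, (64, 128), seed=9, config=cfg)
        b = sm.render_movie(truth, tm, (64, 128), seed=9, config=cfg)
        np.testing.assert_array_equal(a[0], b[0])
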