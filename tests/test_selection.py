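"""Stimulus-frame removal, null symmetrization, tail-ratio FDR and the
peak-consistency and negative-response filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spectramap as sm
from spectramap.selection import (
    fdr_curve,
    flag_negative,
    peak_filter,
    remove_stimulus_frames,
    stimulus_frame_mask,
    symmetrize_control,
)


class TestStimulusFrameRemoval:
    def test_canonical_protocol_masks_each_flash(self, schedule):
        # 100 ms flashes usually fall inside one 420 ms frame, but the
        # onset phase drifts by 0.762 frames per event, so two of the
        # twelve flashes (57.5 s and 107.5 s) straddle a frame boundary
        mask = stimulus_frame_mask(schedule)
        assert mask.sum() == 14
        ft = schedule.frame_times_s
        for _, onset, dur in schedule.events:
            per_flash = np.sum((ft < onset + dur) & (ft + 0.42 > onset))
            assert 1 <= per_flash <= 2

    def test_no_stimuli_no_mask(self):
        sched = sm.StimulusSchedule(events=(), frame_period_s=0.42, n_frames=100)
        assert stimulus_frame_mask(sched).sum() == 0

    def test_masked_frames_linearly_interpolated(self, schedule):
        t = schedule.frame_times_s
        trace = np.sin(0.1 * t)
        trace_art = trace.copy()
        mask = stimulus_frame_mask(schedule)
        trace_art[mask] += 50.0  # huge bleed-through artifact
        cleaned, m = remove_stimulus_frames(trace_art, schedule)
        np.testing.assert_array_equal(m, mask)
        assert np.max(np.abs(cleaned - trace)) < 0.01

    def test_bleed_through_suppressed_in_rendered_movie(self, schedule, cirf_params):
        cfg = sm.SynthConfig(n_neurons=0, background_F=200.0)
        tm = sm.simulate_traces([], schedule, cirf_params, cfg,
                                frame_times_s=schedule.frame_times_s)
        stacks = sm.render_movie([], tm, (32, 32), seed=3, config=cfg,
                                 schedule=schedule, bleed_through=8.0)
        trace = stacks[0].astype(float).mean(axis=(1, 2))
        cleaned, _ = remove_stimulus_frames(trace, schedule)
        resid = cleaned - cleaned.mean()
        assert np.max(np.abs(resid)) < 3 * trace[~stimulus_frame_mask(schedule)].std() + 1e-9


class TestSymmetrization:
    def test_single_roi_emits_24_orderings(self):
        pooled = symmetrize_control(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert pooled.shape == (24, 4)
        assert len(set(map(tuple, pooled))) == 24
        for j in range(4):
            values, counts = np.unique(pooled[:, j], return_counts=True)
            np.testing.assert_array_equal(values, [1, 2, 3, 4])
            np.testing.assert_array_equal(counts, 6)

    def test_channel_marginals_identical(self):
        rng = np.random.default_rng(0)
        pooled = symmetrize_control(rng.standard_normal((50, 4)))
        ref = np.sort(pooled[:, 0])
        for j in range(1, 4):
            np.testing.assert_array_equal(np.sort(pooled[:, j]), ref)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=1, max_value=30))
    def test_pooled_multiset_preserved(self, n):
        """Symmetrization never changes the pooled multiset of all 4N T values."""
        rng = np.random.default_rng(n)
        T = rng.standard_normal((n, 4))
        pooled = symmetrize_control(T)
        assert pooled.shape == (24 * n, 4)
        np.testing.assert_allclose(
            np.sort(np.unique(pooled)), np.sort(np.unique(T))
        )


class TestFdrCurve:
    def test_identical_samples_give_unit_fdr(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        curve = fdr_curve(x, x, level=0.01)
        # tail ratio is exactly 1 at every threshold; no 1% threshold exists
        assert curve.chosen is None
        assert np.nanmin(curve.fdr[np.isfinite(curve.fdr)]) == pytest.approx(1.0)

    def test_separated_mixture_thresholds_below_signal(self):
        rng = np.random.default_rng(2)
        ctrl = rng.standard_normal(20000)
        exp = np.concatenate([ctrl, np.full(300, 50.0)])
        curve = fdr_curve(exp, ctrl, level=0.01)
        assert curve.chosen is not None
        assert curve.chosen <= ctrl.max() + 1e-9
        beyond = curve.thresholds > ctrl.max()
        assert np.all(curve.fdr[beyond] == 0.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fdr_curve(np.array([]), np.ones(5))


class TestPeakFilter:
    def _responder_trace(self, schedule, cirf_params, channel, skip=()):
        t = schedule.frame_times_s
        trace = np.zeros_like(t)
        for k, onset in enumerate(schedule.onsets(channel)):
            if k not in skip:
                trace += sm.cirf(t - onset, cirf_params)
        return trace

    def test_clean_triple_responder_passes_only_its_channel(
        self, schedule, cirf_params
    ):
        trace = self._responder_trace(schedule, cirf_params, "L1")
        n_peaks, passed = peak_filter(trace, schedule)
        assert passed.tolist() == [True, False, False, False]
        assert n_peaks[0] == 3

    def test_missing_one_repetition_fails(self, schedule, cirf_params):
        trace = self._responder_trace(schedule, cirf_params, "L1", skip=(1,))
        _, passed = peak_filter(trace, schedule)
        assert not passed[0]

    def test_low_prominence_secondary_peaks_fail(self, schedule, cirf_params):
        t = schedule.frame_times_s
        onsets = schedule.onsets("L2")
        trace = sm.cirf(t - onsets[0], cirf_params)
        for onset in onsets[1:]:
            trace += 0.2 * sm.cirf(t - onset, cirf_params)
        _, passed = peak_filter(trace, schedule)
        assert not passed[1]

    def test_all_zero_trace_fails_everything(self, schedule):
        _, passed = peak_filter(np.zeros(schedule.n_frames), schedule)
        assert not passed.any()


class TestNegativeFlag:
    def test_inhibited_neuron_flagged(self, schedule, cirf_params):
        nrn = sm.GroundTruthNeuron(
            id=0, z=0, centroid=(30, 30), region="D", sign=-1,
            response_set=frozenset({"L1"}), amplitude={"L1": 0.8},
        )
        cfg = sm.SynthConfig(noise_sd=0.005, drift_amplitude=0.0, seed=4)
        tm = sm.simulate_traces([nrn], schedule, cirf_params, cfg)
        dff = sm.smooth(sm.compute_dff(tm.F, sm.estimate_baseline(tm.F)))
        design = sm.build_design_matrix(schedule, cirf_params)
        reg = sm.regress_all(dff, design)
        thresholds = {"level": 0.01, "L1": 10.0, "L2": 10.0, "L3": 10.0, "L4": 10.0}
        neg = flag_negative(
            reg.T, dff, schedule, thresholds, F=tm.F, design=design
        )
        assert neg[0, 0]
        assert not neg[0, 1:].any()

    def test_positive_responder_not_flagged(self, cohort):
        pos_ids = [
            n.id for n in cohort.truth if n.response_set and n.sign > 0
        ]
        flagged = cohort.sel.negative[pos_ids]
        # a positive responder's channels must never be flagged negative
        assert not flagged.any()

    def test_null_neurons_rarely_flagged(self, cohort):
        null_ids = [n.id for n in cohort.truth if not n.response_set]
        frac = cohort.sel.negative[null_ids].any(axis=1).mean()
        assert frac < 0.01


class TestSelectionOnCohort:
    def test_pass_implies_threshold_and_peaks(self, cohort):
        sel = cohort.sel
        for j, ch in enumerate(sm.CHANNELS):
            th = cohort.thresholds[ch]
            passing = sel.pass_channel[:, j]
            assert np.all(cohort.reg.T[passing, j] >= th)
            assert np.all(sel.n_peaks[passing, j] >= 3)

    def test_raising_amplitudes_never_deselects(self, schedule, cirf_params, design):
        """Monotonicity: stronger responders cannot reduce the selected count."""
        from conftest import analyze_cohort

        atlas = sm.make_atlas((4, 128, 256))
        base = sm.SynthConfig(n_neurons=800, seed=31)
        truth = sm.simulate_ground_truth(base, atlas)
        boosted = []
        for n in truth:
            amp = {c: 3.0 * a for c, a in n.amplitude.items()}
            boosted.append(
                sm.GroundTruthNeuron(
                    id=n.id, z=n.z, centroid=n.centroid, region=n.region,
                    response_set=n.response_set, sign=n.sign,
                    amplitude=amp, baseline_F=n.baseline_F,
                )
            )
        lo = analyze_cohort(truth, schedule, cirf_params, base, design)
        hi = analyze_cohort(boosted, schedule, cirf_params, base, design)
        assert (hi["sel"].tbar > 0).sum() >= (lo["sel"].tbar > 0).sum()
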