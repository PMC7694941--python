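"""Shared fixtures: canonical protocol objects and a mid-sized simulated
cohort analysed once per session (several test modules interrogate it)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

import spectramap as sm
from spectramap.selection import (
    choose_thresholds,
    remove_stimulus_frames,
    select_responders,
    stimulus_frame_mask,
    symmetrize_control,
)


@pytest.fixture(scope="session")
def schedule() -> sm.StimulusSchedule:
    return sm.build_schedule()


@pytest.fixture(scope="session")
def cirf_params() -> sm.CirfParams:
    return sm.CirfParams()


@pytest.fixture(scope="session")
def design(schedule, cirf_params) -> sm.DesignMatrix:
    return sm.build_design_matrix(
        schedule, cirf_params, masked_frames=stimulus_frame_mask(schedule)
    )


@pytest.fixture(scope="session")
def wide_design() -> sm.DesignMatrix:
    """A schedule with 45 s spacing: the kernel tail is ~4e-9 of peak at the
    next onset, so the orthogonality diagnostic sits far below 1e-3."""
    sched = sm.build_schedule(
        "standard", n_reps=2, spacing_s=45.0, rest_s=20.0, n_frames=900
    )
    return sm.build_design_matrix(sched, masked_frames=stimulus_frame_mask(sched))


def analyze_cohort(truth, schedule, cirf_params, cfg, design, ctrl_seed_offset=1000):
    """Trace-level end-to-end analysis of a simulated cohort."""
    sim = sm.simulate_traces(truth, schedule, cirf_params, cfg)
    ctrl_cfg = sm.SynthConfig(**{**cfg.__dict__, "seed": cfg.seed + ctrl_seed_offset})
    ctrl = sm.simulate_traces(
        truth, None, cirf_params, ctrl_cfg, frame_times_s=schedule.frame_times_s
    )

    def process(F):
        cleaned, _ = remove_stimulus_frames(F, schedule)
        F0 = sm.estimate_baseline(cleaned)
        return cleaned, sm.smooth(sm.compute_dff(cleaned, F0))

    F_clean, dff = process(sim.F)
    _, dff_ctrl = process(ctrl.F)
    reg = sm.regress_all(dff, design)
    reg_ctrl = sm.regress_all(dff_ctrl, design)
    thresholds = choose_thresholds(reg.T, symmetrize_control(reg_ctrl.T))
    sel = select_responders(
        reg.T, dff, schedule, thresholds, F=F_clean, design=design
    )
    return dict(
        dff=dff, dff_ctrl=dff_ctrl, reg=reg, reg_ctrl=reg_ctrl,
        thresholds=thresholds, sel=sel,
    )


@dataclass
class Cohort:
    truth: list
    atlas: np.ndarray
    cfg: sm.SynthConfig
    dff: np.ndarray
    reg: sm.RegressionTable
    thresholds: dict
    sel: sm.SelectionTable


@pytest.fixture(scope="session")
def cohort(schedule, cirf_params, design) -> Cohort:
    """3000 neurons at simulator defaults, analysed end to end (trace tier)."""
    cfg = sm.SynthConfig(n_neurons=3000, seed=7)
    atlas = sm.make_atlas((8, 192, 384))
    truth = sm.simulate_ground_truth(cfg, atlas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = analyze_cohort(truth, schedule, cirf_params, cfg, design)
    return Cohort(
        truth=truth, atlas=atlas, cfg=cfg, dff=res["dff"], reg=res["reg"],
        thresholds=res["thresholds"], sel=res["sel"],
    )
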