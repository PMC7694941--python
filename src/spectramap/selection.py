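"""Responder selection: stimulus-frame removal, empirical-null FDR
thresholding, peak-consistency filtering, and negative-response flags.

The null T distribution comes from a control recording (no stimulation)
analysed with the same design matrix; because no channel ordering is
preferable under the null, each control ROI's four T values are pooled over
all 24 permutations, making the null exchangeable across channels.  The
threshold for each channel (and for T4D) is the smallest T at which the
tail ratio

    FDR(t) = [#{ctrl >= t} / N_ctrl] / [#{exp >= t} / N_exp]

drops to the target level (0.01).  On top of the threshold, a channel only
counts as responsive if the max-normalized dF/F0 trace shows a peak of
topographic prominence >= 0.3 in every one of that channel's post-flash
windows (three peaks for three repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .protocol import CHANNELS, StimulusSchedule

__all__ = [
    "FdrCurve",
    "SelectionTable",
    "stimulus_frame_mask",
    "remove_stimulus_frames",
    "symmetrize_control",
    "fdr_curve",
    "choose_thresholds",
    "peak_filter",
    "flag_negative",
    "select_responders",
]


@dataclass
class FdrCurve:
    """Tail-ratio FDR as a function of candidate threshold."""

    thresholds: np.ndarray
    fdr: np.ndarray
    chosen: float | None
    level: float = 0.01

    @property
    def achieved(self) -> float:
        return float(np.nanmin(self.fdr)) if len(self.fdr) else np.inf


@dataclass
class SelectionTable:
    """Per-ROI pass flags, peak counts, negative flags and barcode."""

    pass_threshold: np.ndarray  # (n_rois, 4) bool: T_i >= threshold_i
    n_peaks: np.ndarray  # (n_rois, 4) int
    pass_peaks: np.ndarray  # (n_rois, 4) bool
    pass_channel: np.ndarray  # (n_rois, 4) bool: threshold AND peaks
    negative: np.ndarray  # (n_rois, 4) bool
    tbar: np.ndarray  # (n_rois,) int

    def to_frame(self, roi_ids: np.ndarray | None = None) -> pd.DataFrame:
        ids = np.arange(len(self.tbar)) if roi_ids is None else roi_ids
        data = {"roi_id": ids}
        for j, ch in enumerate(CHANNELS):
            data[f"pass_{ch}"] = self.pass_channel[:, j]
            data[f"n_peaks_{ch}"] = self.n_peaks[:, j]
            data[f"negative_{ch}"] = self.negative[:, j]
        data["tbar"] = self.tbar
        return pd.DataFrame(data)


def stimulus_frame_mask(schedule: StimulusSchedule) -> np.ndarray:
    """Boolean mask of frames whose scan interval overlaps any flash."""
    ft = schedule.frame_times_s
    fp = schedule.frame_period_s
    mask = np.zeros(schedule.n_frames, dtype=bool)
    for _, onset, dur in schedule.events:
        mask |= (ft < onset + dur) & (ft + fp > onset)
    return mask


def remove_stimulus_frames(
    traces: np.ndarray, schedule: StimulusSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Mask flash-contaminated frames and fill them by linear interpolation.

    Returns ``(cleaned, mask)``; works on a single trace or an
    ``(n_rois, n_frames)`` matrix.
    """
    X = np.atleast_2d(np.asarray(traces, dtype=float))
    if X.shape[1] != schedule.n_frames:
        raise ValueError("trace length does not match schedule")
    mask = stimulus_frame_mask(schedule)
    keep = ~mask
    ft = schedule.frame_times_s
    out = X.copy()
    out[:, mask] = np.array(
        [np.interp(ft[mask], ft[keep], row[keep]) for row in X]
    )
    if np.asarray(traces).ndim == 1:
        return out[0], mask
    return out, mask


def symmetrize_control(ctrl_T: np.ndarray) -> np.ndarray:
    """Pool all 24 channel permutations of each control ROI's T 4-vector.

    Output shape ``(24 * n_rois, 4)``; every channel marginal of the pooled
    sample is the same multiset, so the null is exchangeable by construction.
    """
    T = np.atleast_2d(np.asarray(ctrl_T, dtype=float))
    if T.shape[1] != 4:
        raise ValueError("control table must have 4 T values per ROI")
    perms = np.array(list(permutations(range(4))))  # (24, 4)
    return T[:, perms].reshape(-1, 4)


def fdr_curve(
    exp_T: np.ndarray,
    ctrl_T: np.ndarray,
    grid: np.ndarray | None = None,
    level: float = 0.01,
) -> FdrCurve:
    """Empirical tail-ratio FDR over candidate thresholds.

    Both samples are 1-D.  The default grid is the sorted unique
    experimental values (the curve only changes there).  The chosen
    threshold is the smallest grid value with FDR <= level; ``None`` when no
    grid point achieves it.
    """
    exp_T = np.asarray(exp_T, dtype=float).ravel()
    ctrl_T = np.asarray(ctrl_T, dtype=float).ravel()
    if exp_T.size == 0 or ctrl_T.size == 0:
        raise ValueError("both samples must be nonempty")
    if grid is None:
        grid = np.unique(exp_T)
    grid = np.asarray(grid, dtype=float)

    ctrl_sorted = np.sort(ctrl_T)
    exp_sorted = np.sort(exp_T)
    ctrl_tail = ctrl_T.size - np.searchsorted(ctrl_sorted, grid, side="left")
    exp_tail = exp_T.size - np.searchsorted(exp_sorted, grid, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = (ctrl_tail / ctrl_T.size) / (exp_tail / exp_T.size)
    fdr = np.where(exp_tail > 0, fdr, np.inf)

    ok = np.flatnonzero(fdr <= level)
    chosen = float(grid[ok[0]]) if ok.size else None
    return FdrCurve(thresholds=grid, fdr=fdr, chosen=chosen, level=level)


def choose_thresholds(
    exp_T: np.ndarray,
    ctrl_T_sym: np.ndarray,
    level: float = 0.01,
) -> dict[str, float | None]:
    """Per-channel and T4D thresholds at the given FDR level.

    ``exp_T`` is ``(n_rois, 4)``; ``ctrl_T_sym`` is the symmetrized pooled
    null ``(m, 4)``.  The T4D null is the symmetrized control mapped through
    the same Euclidean-norm formula.
    """
    exp_T = np.atleast_2d(exp_T)
    ctrl = np.atleast_2d(ctrl_T_sym)
    out: dict[str, float | None] = {"level": level}
    for j, ch in enumerate(CHANNELS):
        out[ch] = fdr_curve(exp_T[:, j], ctrl[:, j], level=level).chosen
    out["T4D"] = fdr_curve(
        np.linalg.norm(exp_T, axis=1), np.linalg.norm(ctrl, axis=1), level=level
    ).chosen
    return out


def _channel_windows(schedule: StimulusSchedule, channel: str) -> list[tuple[float, float]]:
    """Post-flash windows for a channel: onset to next onset, last capped."""
    onsets = sorted(e[1] for e in schedule.events)
    spacing = onsets[1] - onsets[0] if len(onsets) > 1 else 12.5
    windows = []
    for ch, onset, _ in schedule.events:
        if ch != channel:
            continue
        later = [o for o in onsets if o > onset]
        end = later[0] if later else onset + spacing
        end = min(end, onset + spacing, schedule.duration_s)
        windows.append((onset, end))
    return windows


def peak_filter(
    dFF: np.ndarray,
    schedule: StimulusSchedule,
    prominence: float = 0.3,
    sign: int = +1,
) -> tuple[np.ndarray, np.ndarray]:
    """Count qualifying response peaks per channel window.

    Each trace is divided by its global maximum (of ``sign * dFF``); local
    maxima with prominence >= ``prominence`` are located; a channel passes
    iff every one of its post-flash windows contains at least one peak.
    Returns ``(n_peaks, passed)`` with shapes ``(n_rois, 4)``.  An all-zero
    or non-positive trace fails all channels.
    """
    X = np.atleast_2d(np.asarray(dFF, dtype=float)) * sign
    ft = schedule.frame_times_s
    win_by_ch = {ch: _channel_windows(schedule, ch) for ch in CHANNELS}
    n_rois = X.shape[0]
    n_peaks = np.zeros((n_rois, 4), dtype=int)
    passed = np.zeros((n_rois, 4), dtype=bool)
    for i in range(n_rois):
        m = X[i].max()
        if not m > 0:
            continue
        norm = X[i] / m
        pk, _ = find_peaks(norm, prominence=prominence)
        pk_t = ft[pk]
        for j, ch in enumerate(CHANNELS):
            wins = win_by_ch[ch]
            hits = [np.any((pk_t >= lo) & (pk_t < hi)) for lo, hi in wins]
            n_peaks[i, j] = sum(
                int(np.sum((pk_t >= lo) & (pk_t < hi))) for lo, hi in wins
            )
            passed[i, j] = len(wins) > 0 and all(hits)
    if np.asarray(dFF).ndim == 1:
        return n_peaks[0], passed[0]
    return n_peaks, passed


def flag_negative(
    T: np.ndarray,
    dFF: np.ndarray,
    schedule: StimulusSchedule,
    thresholds: dict[str, float | None],
    prominence: float = 0.3,
    F: np.ndarray | None = None,
    design=None,
) -> np.ndarray:
    """Light-inhibited responders: T_i <= -threshold_i with consistent troughs.

    The criterion mirrors the positive one: the per-channel threshold is
    negated and the peak filter runs on the sign-flipped trace.  A
    low-quantile running baseline tracks inhibition dips (they fill well
    over a tenth of any 21 s window), which flattens negative responses
    out of the standard dF/F0; when the raw ``F`` and the design are
    supplied, the negative test therefore recomputes dF/F0 against a
    median (q = 0.5) running baseline — robust to dips shorter than half
    a window — and rescores T on that trace.
    """
    T = np.atleast_2d(T)
    base = np.atleast_2d(dFF)
    if F is not None and design is not None:
        from .regress import regress_all
        from .traces import compute_dff, estimate_baseline, smooth

        fp = schedule.frame_period_s
        F = np.atleast_2d(F)
        F0 = estimate_baseline(F, frame_period_s=fp, quantile=0.5)
        base = smooth(compute_dff(F, F0), frame_period_s=fp)
        T = regress_all(base, design).T
    _, trough_pass = peak_filter(base, schedule, prominence, sign=-1)
    neg = np.zeros_like(trough_pass)
    for j, ch in enumerate(CHANNELS):
        th = thresholds.get(ch)
        if th is None:
            continue
        neg[:, j] = (T[:, j] <= -th) & trough_pass[:, j]
    return neg


def select_responders(
    T: np.ndarray,
    dFF: np.ndarray,
    schedule: StimulusSchedule,
    thresholds: dict[str, float | None],
    prominence: float = 0.3,
    F: np.ndarray | None = None,
    design=None,
) -> SelectionTable:
    """Combine threshold and peak-consistency criteria into pass flags and Tbar.

    ``F`` and ``design``, when given, enable the robust-baseline rescoring
    of the negative-response test (see :func:`flag_negative`).
    """
    from .classify import tbar_codes

    T = np.atleast_2d(T)
    X = np.atleast_2d(dFF)
    pass_th = np.zeros_like(T, dtype=bool)
    for j, ch in enumerate(CHANNELS):
        th = thresholds.get(ch)
        if th is not None:
            pass_th[:, j] = T[:, j] >= th
    n_peaks, pass_pk = peak_filter(X, schedule, prominence)
    pass_channel = pass_th & pass_pk
    negative = flag_negative(T, X, schedule, thresholds, prominence, F=F, design=design)
    # a neuron carries one response sign: positively selected neurons are
    # never also reported as light-inhibited (strong positive responses
    # induce small negative cross-channel T via the intercept)
    negative &= ~pass_channel.any(axis=1, keepdims=True)
    return SelectionTable(
        pass_threshold=pass_th,
        n_peaks=n_peaks,
        pass_peaks=pass_pk,
        pass_channel=pass_channel,
        negative=negative,
        tbar=tbar_codes(pass_channel),
    )
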