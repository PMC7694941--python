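"""Spectral barcodes (Tbar) and class-level aggregation.

A selected neuron's spectral identity is the 4-bit code
``Tbar = 8*L1 + 4*L2 + 2*L3 + 1*L4`` where bit ``L_i`` is 1 iff the neuron
passed both the T threshold and the peak-consistency filter for that
channel.  Fifteen nonzero codes exist; 8/4/2/1 are the single-wavelength
classes (UV, violet, blue, red respectively) and 0 means nonresponsive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import CHANNELS, StimulusSchedule

__all__ = [
    "TbarCode",
    "tbar",
    "tbar_codes",
    "class_summary",
    "identity_stability",
    "TBAR_WEIGHTS",
]

#: Bit weights of the four channels in protocol order (L1 most significant).
TBAR_WEIGHTS = (8, 4, 2, 1)


@dataclass(frozen=True)
class TbarCode:
    """A spectral barcode and its per-channel bits."""

    value: int
    bits: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        expect = sum(w * int(b) for w, b in zip(TBAR_WEIGHTS, self.bits))
        if self.value != expect:
            raise ValueError(f"value {self.value} inconsistent with bits {self.bits}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(ch for ch, b in zip(CHANNELS, self.bits) if b)


def tbar(pass_channel) -> TbarCode:
    """Barcode for one neuron's four pass flags."""
    bits = tuple(bool(b) for b in pass_channel)
    if len(bits) != 4:
        raise ValueError("expected 4 channel flags")
    return TbarCode(value=sum(w * int(b) for w, b in zip(TBAR_WEIGHTS, bits)), bits=bits)


def tbar_codes(pass_channel: np.ndarray) -> np.ndarray:
    """Vectorized barcode over an ``(n_rois, 4)`` flag matrix."""
    flags = np.atleast_2d(np.asarray(pass_channel, dtype=bool))
    return flags @ np.asarray(TBAR_WEIGHTS)


def class_summary(
    tbar_values: np.ndarray,
    dFF: np.ndarray,
    schedule: StimulusSchedule,
    min_class_size: int = 10,
) -> pd.DataFrame:
    """Per-class counts and mean +/- sd repetition-averaged traces.

    Each neuron's trace is first averaged over the repetition blocks (one
    50 s block per repetition of the four-stimulus train, starting at the
    first onset), then the class mean and sd are taken across neurons at
    each within-block frame.  Classes below ``min_class_size`` are kept in
    the table but flagged ``reported = False``.
    """
    tbar_values = np.asarray(tbar_values)
    X = np.atleast_2d(np.asarray(dFF, dtype=float))
    blocks = _repetition_blocks(X, schedule)

    rows = []
    trace_cols = {}
    for code in np.unique(tbar_values):
        idx = np.flatnonzero(tbar_values == code)
        cls_blocks = blocks[idx]
        rows.append(
            {
                "tbar": int(code),
                "count": len(idx),
                "reported": len(idx) >= min_class_size,
            }
        )
        trace_cols[int(code)] = (
            cls_blocks.mean(axis=0),
            cls_blocks.std(axis=0, ddof=0),
        )
    out = pd.DataFrame(rows)
    out.attrs["block_traces"] = trace_cols
    return out


def _repetition_blocks(X: np.ndarray, schedule: StimulusSchedule) -> np.ndarray:
    """Average each neuron's repetitions into one block: (n_rois, block_len)."""
    order = schedule.channel_order()
    n_per_rep = len(set(order))
    n_reps = max(1, len(order) // n_per_rep)
    onsets = sorted(e[1] for e in schedule.events)
    spacing = onsets[1] - onsets[0] if len(onsets) > 1 else schedule.duration_s
    block_s = n_per_rep * spacing
    fp = schedule.frame_period_s
    block_len = int(round(block_s / fp))
    start = int(np.floor(onsets[0] / fp))
    segs = []
    for r in range(n_reps):
        a = start + r * block_len
        b = min(a + block_len, X.shape[1])
        seg = X[:, a:b]
        if seg.shape[1] < block_len:  # pad truncated last block with nan
            pad = np.full((X.shape[0], block_len - seg.shape[1]), np.nan)
            seg = np.concatenate([seg, pad], axis=1)
        segs.append(seg)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack(segs, axis=0), axis=0)


def identity_stability(
    tbar_standard: np.ndarray,
    tbar_shuffled: np.ndarray,
) -> float:
    """Fraction of ROIs selected under either protocol whose barcodes agree.

    Both arrays index the same ROIs (same order).  ROIs nonresponsive under
    both protocols do not enter the fraction.
    """
    a = np.asarray(tbar_standard)
    b = np.asarray(tbar_shuffled)
    if a.shape != b.shape:
        raise ValueError("selection tables must cover the same ROIs")
    considered = (a > 0) | (b > 0)
    if not considered.any():
        raise ValueError("no ROI selected under either protocol")
    return float(np.mean(a[considered] == b[considered]))
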