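"""Stimulation protocol, calcium impulse response and regression design matrix.

The experiment presents brief LED flashes on four spectral channels (L1 = UV
365 nm, L2 = violet 420 nm, L3 = blue 470 nm, L4 = red 600 nm) to a larva
while a plane is imaged at a fixed frame rate.  The canonical protocol is
12 regularly paced 100 ms flashes, 12.5 s apart, after a 20 s rest, recorded
over 418 frames of 420 ms each (~176 s); one repetition of the four channels
therefore occupies 50 s and the standard run contains three repetitions.

The regression design matrix has one column per channel: the channel's
flash boxcar convolved with the calcium impulse response function (CIRF),
sampled on the frame clock and scaled to unit Euclidean norm.  The 12.5 s
spacing makes the four columns orthogonal for all practical purposes, so
the simple estimator ``beta = G.T @ dff`` is the least-squares fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS",
    "SHUFFLED_ORDER",
    "StimulusSchedule",
    "CirfParams",
    "DesignMatrix",
    "build_schedule",
    "cirf",
    "cirf_peak_time",
    "build_design_matrix",
    "cone_excitation",
    "CONE_PEAKS_NM",
]

#: Stimulus channel names, in protocol order.
CHANNELS = ("L1", "L2", "L3", "L4")

#: Channel order of the shuffled control protocol (three repetitions).
SHUFFLED_ORDER = (
    "L3", "L4", "L2", "L1", "L4", "L3", "L1", "L2", "L2", "L3", "L4", "L1",
)

#: Absorption peaks (nm) of the four zebrafish cone types: UV, S, M, L.
CONE_PEAKS_NM = (362.0, 415.0, 480.0, 570.0)


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed, wavelength-tagged flash events on an acquisition timeline.

    Parameters
    ----------
    events
        ``(channel, onset_s, duration_s)`` triples, sorted by onset.
    frame_period_s
        Duration of one frame scan (0.42 s in the canonical timeline).
    n_frames
        Number of frames in the recording (418 canonically).
    rest_s
        Initial resting time before the first stimulus (20 s).
    """

    events: tuple[tuple[str, float, float], ...]
    frame_period_s: float = 0.42
    n_frames: int = 418
    rest_s: float = 20.0

    def __post_init__(self) -> None:
        total = self.n_frames * self.frame_period_s
        onsets = [e[1] for e in self.events]
        if any(o2 < o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("events must be sorted by onset")
        for ch, onset, dur in self.events:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if onset < self.rest_s:
                raise ValueError(f"onset {onset} s precedes rest period")
            if onset + dur >= total:
                raise ValueError(
                    f"event at {onset} s overruns the {total:.2f} s recording"
                )

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    @property
    def frame_times_s(self) -> np.ndarray:
        """Frame timestamps (frame starts)."""
        return np.arange(self.n_frames) * self.frame_period_s

    def onsets(self, channel: str) -> np.ndarray:
        return np.array([e[1] for e in self.events if e[0] == channel])

    def channel_order(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.events)

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame_period_s": self.frame_period_s,
                "n_frames": self.n_frames,
                "rest_s": self.rest_s,
                "events": [
                    {"channel": c, "onset_s": o, "duration_s": d}
                    for c, o, d in self.events
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSchedule":
        obj = json.loads(text)
        return cls(
            events=tuple(
                (e["channel"], float(e["onset_s"]), float(e["duration_s"]))
                for e in obj["events"]
            ),
            frame_period_s=float(obj["frame_period_s"]),
            n_frames=int(obj["n_frames"]),
            rest_s=float(obj["rest_s"]),
        )


@dataclass(frozen=True)
class CirfParams:
    """Calcium impulse response parameters (seconds)."""

    tau_rise_s: float = 1.5
    tau_decay_s: float = 2.1

    def __post_init__(self) -> None:
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ValueError("CIRF time constants must be positive")
        if self.tau_rise_s == self.tau_decay_s:
            raise ValueError("rise and decay time constants must differ")


@dataclass
class DesignMatrix:
    """Unit-norm regression design, one column per stimulus channel."""

    G: np.ndarray
    column_channels: tuple[str, ...]
    frame_times_s: np.ndarray
    orthogonality: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.G.shape[1] != len(self.column_channels):
            raise ValueError("column count does not match channel labels")


def build_schedule(
    pattern: str | list[str] | tuple[str, ...] = "standard",
    n_reps: int = 3,
    spacing_s: float = 12.5,
    rest_s: float = 20.0,
    flash_s: float = 0.1,
    frame_period_s: float = 0.42,
    n_frames: int = 418,
) -> StimulusSchedule:
    """Build a flash schedule on the acquisition timeline.

    ``pattern`` is ``"standard"`` (channels L1..L4 cycled ``n_reps`` times),
    ``"shuffled"`` (the fixed control order, three repetitions), or an
    explicit list of channel names.  Event ``k`` starts at
    ``rest_s + k * spacing_s`` and lasts ``flash_s``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(pattern, str):
        if pattern == "standard":
            order = CHANNELS * n_reps
        elif pattern == "shuffled":
            if n_reps != 3:
                raise ValueError("the shuffled protocol is defined for n_reps=3")
            order = SHUFFLED_ORDER
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
    else:
        order = tuple(pattern)

    total = n_frames * frame_period_s
    last_end = rest_s + (len(order) - 1) * spacing_s + flash_s
    if last_end >= total:
        raise ValueError(
            f"schedule ends at {last_end:.2f} s, beyond the {total:.2f} s recording"
        )
    events = tuple(
        (ch, rest_s + k * spacing_s, flash_s) for k, ch in enumerate(order)
    )
    return StimulusSchedule(
        events=events,
        frame_period_s=frame_period_s,
        n_frames=n_frames,
        rest_s=rest_s,
    )


def cirf(t: np.ndarray | float, params: CirfParams = CirfParams()) -> np.ndarray:
    """Calcium impulse response: peak-normalized difference of exponentials.

    ``k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)`` for ``t > 0``, zero for
    ``t <= 0``, scaled so the maximum equals 1.
    """
    t = np.asarray(t, dtype=float)
    tr, td = params.tau_rise_s, params.tau_decay_s
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(-tp / td) - np.exp(-tp / tr)
    t_peak = cirf_peak_time(params)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return out / peak


def cirf_peak_time(params: CirfParams = CirfParams()) -> float:
    """Closed-form time of the CIRF maximum."""
    tr, td = params.tau_rise_s, params.tau_decay_s
    return tr * td / (td - tr) * np.log(td / tr)


def build_design_matrix(
    schedule: StimulusSchedule,
    params: CirfParams = CirfParams(),
    grid_step_s: float = 0.01,
    masked_frames: np.ndarray | None = None,
    orthogonality_tol: float = 1e-2,
) -> DesignMatrix:
    """Convolve each channel's flash boxcar with the CIRF and sample it.

    The boxcar (1 during flashes, 0 elsewhere) lives on a fine grid
    (``grid_step_s``, default 10 ms, resolving the 100 ms flash), is
    convolved with the CIRF and sampled at frame times.  When
    ``masked_frames`` marks stimulus-contaminated frames, the sampled
    columns are linearly interpolated across them — the same treatment the
    traces receive.  Columns are scaled to unit L2 norm; the maximum
    off-diagonal of ``G.T @ G`` is stored as an orthogonality diagnostic
    (a warning, not an error, if above tolerance).
    """
    ft = schedule.frame_times_s
    n_grid = int(np.ceil(schedule.duration_s / grid_step_s)) + 1
    tg = np.arange(n_grid) * grid_step_s
    kernel = cirf(tg, params)

    cols = np.zeros((schedule.n_frames, len(CHANNELS)))
    for j, ch in enumerate(CHANNELS):
        box = np.zeros(n_grid)
        for c, onset, dur in schedule.events:
            if c == ch:
                box[(tg >= onset) & (tg < onset + dur)] = 1.0
        conv = np.convolve(box, kernel)[:n_grid] * grid_step_s
        cols[:, j] = np.interp(ft, tg, conv)

    if masked_frames is not None:
        masked_frames = np.asarray(masked_frames, dtype=bool)
        keep = ~masked_frames
        for j in range(cols.shape[1]):
            cols[masked_frames, j] = np.interp(
                ft[masked_frames], ft[keep], cols[keep, j]
            )

    norms = np.linalg.norm(cols, axis=0)
    used = norms > 0
    cols[:, used] /= norms[used]  # channels absent from the schedule stay zero

    gram = cols.T @ cols
    ortho = float(np.max(np.abs(gram - np.diag(np.diag(gram)))))
    if ortho > orthogonality_tol:
        warnings.warn(
            f"design matrix orthogonality diagnostic {ortho:.2e} exceeds "
            f"tolerance {orthogonality_tol:.2e}",
            stacklevel=2,
        )
    return DesignMatrix(
        G=cols,
        column_channels=CHANNELS,
        frame_times_s=ft,
        orthogonality=ortho,
    )


def _govardovskii_a1(wavelength_nm: np.ndarray, lambda_max: float) -> np.ndarray:
    """Alpha-band visual pigment absorbance template (A1 chromophore)."""
    x = lambda_max / np.asarray(wavelength_nm, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    return 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (0.922 - x)) + np.exp(C * (1.104 - x)) + D
    )


def cone_excitation(
    led_band: tuple[float, float],
    cone_peaks_nm: tuple[float, ...] = CONE_PEAKS_NM,
    clip_below: float = 0.01,
) -> np.ndarray:
    """Relative excitation of each cone type by a rectangular LED band.

    ``led_band`` is ``(center_nm, fwhm_nm)``.  The pigment absorbance
    template is integrated over the band for each cone, the result is
    normalized so the maximally excited cone equals 1, and coefficients
    below ``clip_below`` are zeroed.
    """
    center, fwhm = led_band
    if not (300.0 <= center <= 700.0):
        raise ValueError("LED band center must lie within 300-700 nm")
    lo, hi = center - fwhm / 2.0, center + fwhm / 2.0
    if lo < 250.0 or hi > 800.0:
        raise ValueError("LED band extends outside the template validity range")
    grid = np.linspace(lo, hi, 201)
    coef = np.array(
        [np.trapezoid(_govardovskii_a1(grid, lm), grid) for lm in cone_peaks_nm]
    )
    coef = coef / coef.max()
    coef[coef < clip_below] = 0.0
    return coef
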