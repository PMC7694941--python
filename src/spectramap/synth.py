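"""Ground-truthed synthetic data: cohorts, traces, movies and a toy atlas.

Emulates whole-CNS two-photon recordings of a nuclear-localized calcium
indicator during spectral flash stimulation: a small minority (~2% by
default) of neurons respond to one or more of the four LED channels with
stimulus-locked transients shaped by the calcium impulse response, on top
of slow baseline drift and shot-like noise.  A rare subset responds
negatively (light-inhibited).  Two fidelity tiers exist: fast trace-level
simulation (Gaussian noise on F) and full movie rendering (Gaussian nuclei,
sqrt-scaled noise, optional stimulus bleed-through) for exercising
segmentation and frame removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import CHANNELS, CirfParams, StimulusSchedule, cirf
from .traces import TraceMatrix

__all__ = [
    "SynthConfig",
    "GroundTruthNeuron",
    "make_atlas",
    "simulate_ground_truth",
    "truth_manifest",
    "simulate_traces",
    "render_movie",
    "write_movie",
]


@dataclass
class SynthConfig:
    """Simulation parameters; a fixed ``seed`` fixes all randomness.

    Fractions are of the total population (``responder_fraction``) or of
    the responder subset (``multi_channel_fraction``,
    ``negative_fraction``).  Response amplitude is a neuron-level property:
    each responder draws one log-normal scale (``amplitude_median``,
    ``amplitude_sigma``, dF/F0 peak units) modulated per channel by a much
    narrower log-normal factor (``channel_sigma``) — multi-wavelength
    neurons respond with comparable amplitude on their effective channels,
    matching the relative-prominence contract of the peak-consistency
    filter (a channel below 30% of a neuron's maximum response is by
    construction undetectable).  Amplitudes are floored at
    ``amplitude_floor_snr`` times the noise sd so default responders are
    well separated from the noise; ``noise_sd`` is in dF/F0 units
    (converted to fluorescence by the baseline).
    """

    n_neurons: int = 1000
    responder_fraction: float = 0.02
    multi_channel_fraction: float = 0.3
    negative_fraction: float = 0.02
    noise_sd: float = 0.05
    amplitude_median: float = 0.8
    amplitude_sigma: float = 0.4
    channel_sigma: float = 0.15
    amplitude_floor_snr: float = 5.0
    drift_amplitude: float = 0.05
    drift_timescale_s: float = 60.0
    baseline_F: float = 2000.0
    background_F: float = 50.0
    nucleus_sigma_px: float = 1.8
    min_spacing_diameters: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("responder_fraction", "multi_channel_fraction", "negative_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be nonnegative")


@dataclass
class GroundTruthNeuron:
    """One simulated neuron and its spectral identity."""

    id: int
    z: int
    centroid: tuple[int, int]  # (row, col)
    region: str
    response_set: frozenset = field(default_factory=frozenset)
    sign: int = +1
    amplitude: dict = field(default_factory=dict)  # channel -> dF/F0 peak
    baseline_F: float = 2000.0

    @property
    def tbar(self) -> int:
        from .classify import TBAR_WEIGHTS

        return sum(
            w for w, ch in zip(TBAR_WEIGHTS, CHANNELS) if ch in self.response_set
        )


def make_atlas(dims: tuple[int, int, int] = (8, 128, 256), seed: int = 0) -> np.ndarray:
    """Toy CNS label volume: six contiguous slabs along the rostro-caudal axis.

    Codes 1..6 = T, E, D, M, R, S; the eyes (E) are two lateral lobes beside
    the telencephalon/diencephalon; 0 is background.  Deterministic given
    ``dims`` (the ``seed`` argument is accepted for interface symmetry; the
    slab layout has no random component).
    """
    nz, nr, nc = dims
    if min(dims) < 1:
        raise ValueError("dims must be positive")
    vol = np.zeros(dims, dtype=np.uint8)
    # rostro-caudal (column) extents as fractions of width
    bounds = {"T": (0.00, 0.15), "D": (0.15, 0.35), "M": (0.35, 0.60),
              "R": (0.60, 0.80), "S": (0.80, 1.00)}
    mid = nr // 2
    body_half = max(1, int(0.30 * nr))
    for name, (a, b) in bounds.items():
        c0, c1 = int(a * nc), max(int(a * nc) + 1, int(b * nc))
        vol[:, mid - body_half : mid + body_half, c0:c1] = {
            "T": 1, "D": 3, "M": 4, "R": 5, "S": 6
        }[name]
    # eyes: lateral lobes flanking the T/D boundary
    e0, e1 = int(0.05 * nc), max(int(0.05 * nc) + 1, int(0.30 * nc))
    eye_half = max(1, int(0.12 * nr))
    vol[:, mid - body_half - eye_half : mid - body_half, e0:e1] = 2
    vol[:, mid + body_half : mid + body_half + eye_half, e0:e1] = 2
    return vol


def _sample_centroids(
    rng: np.random.Generator,
    n: int,
    n_planes: int,
    shape: tuple[int, int],
    min_dist: float,
    margin: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing with a per-plane occupancy grid; rejects impossible density."""
    nr, nc = shape
    cell = max(min_dist, 1.0)
    gw = int(np.ceil((nc - 2 * margin) / cell)) + 1
    gh = int(np.ceil((nr - 2 * margin) / cell)) + 1
    grids = [dict() for _ in range(n_planes)]
    zs = np.empty(n, dtype=int)
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "requested neuron density undercuts the minimum spacing"
            )
        z = int(rng.integers(n_planes))
        r = rng.uniform(margin, nr - margin)
        c = rng.uniform(margin, nc - margin)
        gi, gj = int((r - margin) / cell), int((c - margin) / cell)
        ok = True
        g = grids[z]
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for (rr, cc) in g.get((gi + di, gj + dj), ()):
                    if (rr - r) ** 2 + (cc - c) ** 2 < min_dist**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        g.setdefault((gi, gj), []).append((r, c))
        zs[placed] = z
        pts[placed] = (r, c)
        placed += 1
    return zs, np.round(pts).astype(int)


def simulate_ground_truth(
    config: SynthConfig,
    atlas: np.ndarray,
    margin: int | None = None,
) -> list[GroundTruthNeuron]:
    """Draw a cohort of neurons with known spectral identities.

    Centroids are placed at least ``min_spacing_diameters`` nucleus
    diameters apart within each plane; responders, their channel subsets,
    signs and amplitudes follow the configured fractions.  Negative
    responders are drawn preferentially from neurons falling in the
    diencephalic slab (a stand-in for the pineal area where inhibitory
    light responses are seen).
    """
    if atlas.size == 0:
        raise ValueError("atlas must be nonempty")
    if margin is None:
        # keep nuclei renderable: blob patches extend 4 sigma from the centroid
        margin = int(np.ceil(4 * config.nucleus_sigma_px)) + 1
    rng = np.random.default_rng(config.seed)
    nz, nr, nc = atlas.shape
    diameter = 2 * config.nucleus_sigma_px
    min_dist = config.min_spacing_diameters * diameter
    zs, pts = _sample_centroids(rng, config.n_neurons, nz, (nr, nc), min_dist, margin)

    from .anatomy import REGION_NAMES

    n = config.n_neurons
    responder = rng.random(n) < config.responder_fraction
    amp_floor = config.amplitude_floor_snr * config.noise_sd

    neurons: list[GroundTruthNeuron] = []
    resp_idx = np.flatnonzero(responder)
    multi = rng.random(len(resp_idx)) < config.multi_channel_fraction
    regions = np.array(
        [REGION_NAMES.get(int(atlas[z, r, c]), "") for z, (r, c) in zip(zs, pts)]
    )
    # negatives preferentially in the diencephalon
    neg = np.zeros(len(resp_idx), dtype=bool)
    n_neg = int(round(config.negative_fraction * len(resp_idx)))
    if n_neg:
        in_d = np.flatnonzero(regions[resp_idx] == "D")
        pool = in_d if len(in_d) >= n_neg else np.arange(len(resp_idx))
        neg[rng.choice(pool, size=n_neg, replace=False)] = True

    resp_info = {}
    for k, i in enumerate(resp_idx):
        n_ch = 1 if not multi[k] else int(rng.integers(2, 5))
        chans = rng.choice(len(CHANNELS), size=n_ch, replace=False)
        scale = np.exp(
            np.log(config.amplitude_median)
            + config.amplitude_sigma * rng.standard_normal()
        )
        amps = np.maximum(
            scale * np.exp(config.channel_sigma * rng.standard_normal(n_ch)),
            amp_floor,
        )
        sign = -1 if neg[k] else +1
        if sign < 0:
            # fluorescence cannot drop below zero: inhibition is capped
            # at 90% baseline suppression
            amps = np.minimum(amps, 0.9)
        resp_info[i] = (
            frozenset(CHANNELS[j] for j in chans),
            {CHANNELS[j]: float(a) for j, a in zip(chans, amps)},
            sign,
        )

    for i in range(n):
        rset, amps, sign = resp_info.get(i, (frozenset(), {}, +1))
        neurons.append(
            GroundTruthNeuron(
                id=i,
                z=int(zs[i]),
                centroid=(int(pts[i, 0]), int(pts[i, 1])),
                region=str(regions[i]),
                response_set=rset,
                sign=sign,
                amplitude=amps,
                baseline_F=config.baseline_F,
            )
        )
    return neurons


def truth_manifest(neurons: list[GroundTruthNeuron]) -> pd.DataFrame:
    """Ground-truth table: one row per neuron."""
    return pd.DataFrame(
        {
            "id": [n.id for n in neurons],
            "z": [n.z for n in neurons],
            "row": [n.centroid[0] for n in neurons],
            "col": [n.centroid[1] for n in neurons],
            "region": [n.region for n in neurons],
            "channels": ["+".join(sorted(n.response_set)) for n in neurons],
            "sign": [n.sign for n in neurons],
            "amplitude": [
                "+".join(f"{n.amplitude[c]:.4f}" for c in sorted(n.amplitude))
                for n in neurons
            ],
            "tbar": [n.tbar for n in neurons],
        }
    )


def response_profile(
    neuron: GroundTruthNeuron,
    schedule: StimulusSchedule | None,
    cirf_params: CirfParams,
    t: np.ndarray,
) -> np.ndarray:
    """Noise-free dF/F0 response of one neuron (zero for non-responders)."""
    resp = np.zeros_like(t)
    if schedule is not None:
        for ch in neuron.response_set:
            amp = neuron.amplitude[ch]
            for onset in schedule.onsets(ch):
                resp += amp * cirf(t - onset, cirf_params)
    return neuron.sign * resp


def simulate_traces(
    truth: list[GroundTruthNeuron],
    schedule: StimulusSchedule | None,
    cirf_params: CirfParams = CirfParams(),
    config: SynthConfig = SynthConfig(),
    frame_times_s: np.ndarray | None = None,
) -> TraceMatrix:
    """Trace-level simulation of raw fluorescence F(t) for a cohort.

    ``F = baseline * (1 + drift + sign * sum_flash amp * CIRF(t - onset))
    + noise`` with zero-mean Gaussian noise of sd ``noise_sd * baseline``.
    Passing ``schedule=None`` yields a matched no-stimulus control
    recording of the same cohort.
    """
    if frame_times_s is None:
        if schedule is None:
            raise ValueError("need a schedule or explicit frame times")
        t = schedule.frame_times_s
    else:
        t = np.asarray(frame_times_s, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(truth)
    nt = len(t)
    baseline = np.array([nrn.baseline_F for nrn in truth])[:, None]
    # drift: three low-frequency harmonics with per-neuron random phases
    modulation = np.ones((n, nt))
    if config.drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=(n, 3))
        for k in (1, 2, 3):
            modulation += (config.drift_amplitude / (1.5 * k)) * np.sin(
                2 * np.pi * k * t[None, :] / config.drift_timescale_s
                + phases[:, k - 1 : k]
            )
    for i, nrn in enumerate(truth):
        if nrn.response_set:
            modulation[i] += response_profile(nrn, schedule, cirf_params, t)
    noise = rng.standard_normal((n, nt))
    F = baseline * np.maximum(modulation, 0.01) + (
        config.noise_sd * baseline
    ) * noise
    return TraceMatrix(frame_times_s=t, F=F)


def render_movie(
    truth: list[GroundTruthNeuron],
    traces: TraceMatrix,
    plane_dims: tuple[int, int],
    psf_sigma: float | None = None,
    seed: int = 0,
    config: SynthConfig = SynthConfig(),
    schedule: StimulusSchedule | None = None,
    bleed_through: float = 0.0,
    overlap_warn_dist: float = 3.0,
    planes: list[int] | None = None,
    shot_noise: bool = True,
) -> dict[int, np.ndarray]:
    """Render per-plane frame stacks from simulated traces.

    Each neuron is a 2-D Gaussian nucleus (sigma ``psf_sigma``, default the
    configured nucleus sigma) whose integrated brightness follows its
    F trace; shot-like noise (Gaussian, sd = sqrt(mean)) is added per
    pixel on top of a flat background.  With ``bleed_through > 0`` and a
    schedule, flash-overlapping frames get a global additive offset of
    ``bleed_through * sqrt(background)`` to exercise stimulus-frame
    removal.  Returns ``{z: stack}`` with stacks ``(n_frames, H, W)``
    uint16.
    """
    import warnings

    H, W = plane_dims
    sig = config.nucleus_sigma_px if psf_sigma is None else psf_sigma
    half = int(np.ceil(4 * sig))
    for nrn in truth:
        r, c = nrn.centroid
        if not (half <= r < H - half and half <= c < W - half):
            raise ValueError(f"neuron {nrn.id} centroid too close to plane border")
    # pairwise proximity warning within planes
    by_plane: dict[int, list[GroundTruthNeuron]] = {}
    for nrn in truth:
        by_plane.setdefault(nrn.z, []).append(nrn)
    for z, group in by_plane.items():
        pts = np.array([g.centroid for g in group], dtype=float)
        if len(pts) > 1:
            d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if d2.min() < overlap_warn_dist**2:
                warnings.warn(f"overlapping nuclei in plane {z}", stacklevel=2)

    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    blob = np.exp(-(yy**2 + xx**2) / (2 * sig**2))
    blob /= blob.sum()

    mask = None
    if bleed_through > 0 and schedule is not None:
        from .selection import stimulus_frame_mask

        mask = stimulus_frame_mask(schedule)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    id_to_row = {nrn.id: i for i, nrn in enumerate(truth)}
    n_frames = traces.n_frames
    if planes is None:
        planes = sorted(by_plane) if by_plane else [0]
    stacks: dict[int, np.ndarray] = {}
    for z in planes:
        mean = np.full((n_frames, H, W), float(config.background_F))
        for nrn in by_plane.get(z, ()):
            r, c = nrn.centroid
            tr = traces.F[id_to_row[nrn.id]]
            mean[:, r - half : r + half + 1, c - half : c + half + 1] += (
                tr[:, None, None] * blob[None]
            )
        if mask is not None:
            mean[mask] += bleed_through * np.sqrt(config.background_F)
        if shot_noise:
            mean += np.sqrt(np.maximum(mean, 0)) * rng.standard_normal(mean.shape)
        stacks[z] = np.clip(mean, 0, 65535).astype(np.uint16)
    return stacks


def write_movie(stacks: dict[int, np.ndarray], out_dir, prefix: str = "plane") -> list:
    """Write each plane stack as an ImageJ-compatible multi-page TIFF."""
    import tifffile
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for z, stack in sorted(stacks.items()):
        p = out_dir / f"{prefix}_z{z:03d}.tif"
        tifffile.imwrite(p, stack, imagej=True)
        paths.append(p)
    return paths
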