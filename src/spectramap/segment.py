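"""Nuclear ROI detection on the temporal MIP and fixed-footprint extraction.

Nuclei of the nuclear-localized indicator appear as bright blobs on the
maximum-intensity projection of each plane's frame stack.  Detection is a
standard blob pipeline — Gaussian band-pass (difference of Gaussians),
quantile threshold, non-maximum suppression — and every accepted nucleus
gets the same 13-pixel diamond footprint (rows of width 1, 3, 5, 3, 1
centered on the centroid) over which raw fluorescence is summed per frame.
Footprints within a plane are kept pairwise disjoint by greedily dropping
the dimmer member of any conflicting pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

__all__ = [
    "RoiTable",
    "SegmentationParams",
    "max_projection",
    "detect_nuclei",
    "cluster_footprint",
    "resolve_overlaps",
    "extract_traces",
    "segment_plane",
    "FOOTPRINT_OFFSETS",
]

#: (row, col) offsets of the 13-pixel diamond footprint (widths 1,3,5,3,1).
FOOTPRINT_OFFSETS = tuple(
    (dr, dc)
    for dr, width in zip((-2, -1, 0, 1, 2), (1, 3, 5, 3, 1))
    for dc in range(-(width // 2), width // 2 + 1)
)
assert len(FOOTPRINT_OFFSETS) == 13


@dataclass
class SegmentationParams:
    """Blob-detection knobs; sigmas scale with the expected nucleus radius."""

    nucleus_radius_px: float = 2.5
    min_distance_px: int = 4
    threshold_quantile: float = 0.95
    noise_k: float = 6.0

    @property
    def sigma_low(self) -> float:
        return self.nucleus_radius_px / 1.5

    @property
    def sigma_high(self) -> float:
        return 2.0 * self.nucleus_radius_px


@dataclass
class RoiTable:
    """Segmented nuclei of one or more planes."""

    ids: np.ndarray
    z: np.ndarray
    centroids: np.ndarray  # (n, 2) int (row, col)
    footprints: np.ndarray  # (n, 13, 2) int
    mip_intensity: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.ids,
                "z": self.z,
                "row": self.centroids[:, 0],
                "col": self.centroids[:, 1],
                "mip_intensity": (
                    self.mip_intensity
                    if self.mip_intensity is not None
                    else np.full(len(self.ids), np.nan)
                ),
            }
        )


def max_projection(stack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over time."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (n_frames, H, W) with at least one frame")
    return stack.max(axis=0)


def detect_nuclei(
    mip: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Centroids of candidate nuclei on a MIP image.

    Local maxima of the difference-of-Gaussians band-pass, above a
    threshold, separated by at least ``min_distance_px``.  The threshold is
    the larger of the configured intensity quantile of the band-passed
    image and a robust noise floor (median + ``noise_k`` robust sd), so it
    adapts to both densely and sparsely populated fields.  Deterministic;
    may return zero detections.
    """
    mip = np.asarray(mip, dtype=float)
    if mip.size == 0:
        raise ValueError("empty image")
    dog = gaussian_filter(mip, params.sigma_low) - gaussian_filter(
        mip, params.sigma_high
    )
    med = np.median(dog)
    mad_sigma = 1.4826 * np.median(np.abs(dog - med))
    thr = max(
        np.quantile(dog, params.threshold_quantile),
        med + params.noise_k * mad_sigma,
    )
    if dog.max() <= thr:
        return np.empty((0, 2), dtype=int)
    peaks = peak_local_max(
        dog,
        min_distance=params.min_distance_px,
        threshold_abs=thr,
        exclude_border=2,
    )
    return peaks.astype(int)


def cluster_footprint(
    centroid: tuple[int, int], image_shape: tuple[int, int]
) -> np.ndarray:
    """The 13-pixel diamond around a centroid; rejects border-adjacent ROIs."""
    r, c = int(centroid[0]), int(centroid[1])
    H, W = image_shape
    if not (2 <= r < H - 2 and 2 <= c < W - 2):
        raise ValueError(f"centroid {centroid} closer than 2 px to the border")
    return np.array([(r + dr, c + dc) for dr, dc in FOOTPRINT_OFFSETS], dtype=int)


def resolve_overlaps(
    centroids: np.ndarray, brightness: np.ndarray
) -> np.ndarray:
    """Indices of ROIs to keep so footprints are pairwise disjoint.

    Greedy from brightest: an ROI is dropped if any of its 13 pixels is
    already claimed by a brighter kept ROI.
    """
    order = np.argsort(-np.asarray(brightness, dtype=float), kind="stable")
    claimed: set[tuple[int, int]] = set()
    keep = []
    for i in order:
        r, c = centroids[i]
        pix = [(r + dr, c + dc) for dr, dc in FOOTPRINT_OFFSETS]
        if any(p in claimed for p in pix):
            continue
        claimed.update(pix)
        keep.append(i)
    return np.sort(np.array(keep, dtype=int))


def segment_plane(
    stack: np.ndarray,
    z: int = 0,
    params: SegmentationParams = SegmentationParams(),
    id_offset: int = 0,
) -> RoiTable:
    """MIP, detect, footprint and overlap-resolve one plane's stack."""
    mip = max_projection(stack)
    centroids = detect_nuclei(mip, params)
    H, W = mip.shape
    valid = [
        i
        for i, (r, c) in enumerate(centroids)
        if 2 <= r < H - 2 and 2 <= c < W - 2
    ]
    centroids = centroids[valid]
    bright = np.array(
        [
            mip[tuple(cluster_footprint((r, c), (H, W)).T)].mean()
            for r, c in centroids
        ]
    )
    if len(centroids):
        keep = resolve_overlaps(centroids, bright)
        centroids, bright = centroids[keep], bright[keep]
    foot = np.array(
        [cluster_footprint((r, c), (H, W)) for r, c in centroids], dtype=int
    ).reshape(len(centroids), 13, 2)
    return RoiTable(
        ids=id_offset + np.arange(len(centroids)),
        z=np.full(len(centroids), z, dtype=int),
        centroids=np.asarray(centroids, dtype=int).reshape(-1, 2),
        footprints=foot,
        mip_intensity=bright,
    )


def extract_traces(stack: np.ndarray, roi_table: RoiTable) -> np.ndarray:
    """Raw F(t): fluorescence summed over each ROI's 13-pixel footprint.

    Returns ``(n_rois, n_frames)``; the stack must belong to the single
    plane the table's ROIs live in.
    """
    stack = np.asarray(stack, dtype=float)
    n_frames, H, W = stack.shape
    flat = stack.reshape(n_frames, H * W)
    out = np.empty((len(roi_table), n_frames))
    for i, fp in enumerate(roi_table.footprints):
        idx = fp[:, 0] * W + fp[:, 1]
        out[i] = flat[:, idx].sum(axis=1)
    return out
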