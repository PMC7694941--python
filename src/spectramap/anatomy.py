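"""Region assignment from a label volume and per-larva anatomical tallies.

Regions follow the larval CNS subdivision used throughout: T telencephalon,
E eyes, D diencephalon, M mesencephalon, R rhombencephalon, S spinal cord,
encoded 1..6 in the label volume (0 = background).  Distributions are
normalized to 1 within each larva across regions, and the cross-larva mean
and standard error include larvae that contributed zero neurons to a class
as all-zero distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REGION_CODES", "REGION_NAMES", "assign_regions", "tally"]

REGION_CODES = {"T": 1, "E": 2, "D": 3, "M": 4, "R": 5, "S": 6}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


def assign_regions(
    centroids: np.ndarray,
    label_volume: np.ndarray,
) -> np.ndarray:
    """Region label at each ROI centroid voxel.

    ``centroids`` is ``(n, 3)`` as ``(z, row, col)`` in atlas voxel
    coordinates; returns an array of region letters, with ``""`` for
    background or out-of-volume centroids (a warning is emitted for the
    latter).
    """
    pts = np.atleast_2d(np.asarray(centroids))
    vol = np.asarray(label_volume)
    out = np.empty(len(pts), dtype=object)
    n_outside = 0
    for i, (z, r, c) in enumerate(np.round(pts).astype(int)):
        if 0 <= z < vol.shape[0] and 0 <= r < vol.shape[1] and 0 <= c < vol.shape[2]:
            out[i] = REGION_NAMES.get(int(vol[z, r, c]), "")
        else:
            out[i] = ""
            n_outside += 1
    if n_outside:
        import warnings

        warnings.warn(f"{n_outside} centroid(s) outside the label volume", stacklevel=2)
    return out.astype(str)


def tally(
    table: pd.DataFrame,
    group_by: str = "tbar",
    larvae: list | None = None,
    regions: tuple[str, ...] = tuple(REGION_CODES),
) -> pd.DataFrame:
    """Per-larva-normalized regional distribution of each class.

    ``table`` needs columns ``larva``, ``region`` and the ``group_by``
    column (e.g. ``tbar`` or a channel flag).  For each class, each larva's
    counts over regions are normalized to sum to 1 (larvae with no neuron
    in the class contribute an all-zero distribution), then the mean and
    standard error (ddof=1, n = number of larvae) are taken across larvae.
    """
    if larvae is None:
        larvae = sorted(table["larva"].unique())
    n_larvae = len(larvae)
    if n_larvae < 1:
        raise ValueError("need at least one larva")

    rows = []
    for cls, sub in table.groupby(group_by):
        fracs = np.zeros((n_larvae, len(regions)))
        for i, lv in enumerate(larvae):
            counts = np.array(
                [np.sum((sub["larva"] == lv) & (sub["region"] == rg)) for rg in regions],
                dtype=float,
            )
            tot = counts.sum()
            if tot > 0:
                fracs[i] = counts / tot
        mean = fracs.mean(axis=0)
        if n_larvae > 1:
            sem = fracs.std(axis=0, ddof=1) / np.sqrt(n_larvae)
        else:
            sem = np.zeros(len(regions))
        for j, rg in enumerate(regions):
            rows.append(
                {
                    group_by: cls,
                    "region": rg,
                    "mean_fraction": mean[j],
                    "stderr": sem[j],
                    "n_larvae": n_larvae,
                }
            )
    return pd.DataFrame(rows)
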