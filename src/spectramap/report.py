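"""Pipeline orchestration, ranked heatmaps, summary tables and manifests.

``run_pipeline`` wires the stages end to end on synthetic data — simulate
(traces or full movies), segment, compute dF/F0, regress, select at 1% FDR
against a matched no-stimulus control, barcode, tally by region — writing
CSV tables, a thresholds JSON, a ranked-heatmap PNG and a run manifest
sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import assign_regions, tally
from .classify import class_summary
from .protocol import (
    CHANNELS,
    CirfParams,
    build_design_matrix,
    build_schedule,
)
from .regress import regress_all
from .segment import SegmentationParams, extract_traces, segment_plane
from .selection import (
    choose_thresholds,
    remove_stimulus_frames,
    select_responders,
    symmetrize_control,
)
from .synth import (
    SynthConfig,
    make_atlas,
    render_movie,
    simulate_ground_truth,
    simulate_traces,
    truth_manifest,
)
from .traces import compute_dff, estimate_baseline, smooth

__all__ = ["DEFAULT_CONFIG", "load_config", "rank_heatmap", "save_heatmap", "run_pipeline"]

log = logging.getLogger("spectramap")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


DEFAULT_CONFIG: dict = {
    "protocol": {
        "pattern": "standard",
        "n_reps": 3,
        "spacing_s": 12.5,
        "rest_s": 20.0,
        "flash_s": 0.1,
        "frame_period_s": 0.42,
        "n_frames": 418,
    },
    "cirf": {"tau_rise_s": 1.5, "tau_decay_s": 2.1},
    "synth": {
        "n_neurons": 500,
        "responder_fraction": 0.02,
        "atlas_dims": [4, 128, 256],
        "mode": "traces",  # "traces" or "movie"
        "bleed_through": 0.0,
    },
    "baseline": {"window_s": 21.0, "step_s": 0.84, "quantile": 0.10},
    "smooth": {"window_s": 2.1},
    "segmentation": {
        "nucleus_radius_px": 2.5,
        "min_distance_px": 4,
        "threshold_quantile": 0.95,
    },
    "selection": {"level": 0.01, "prominence": 0.3},
    "report": {"top_k": 600, "ranking": "T4D", "min_class_size": 10},
}


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, overlaid with a YAML/JSON file when given."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _deep_merge(cfg, yaml.safe_load(fh) or {})
    return cfg


def rank_heatmap(
    dFF: np.ndarray,
    stats: np.ndarray,
    top_k: int = 600,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows of ``dFF`` for the ``top_k`` ROIs ranked by a statistic.

    Ties break by ROI index (ascending) so the ordering is deterministic.
    Returns ``(order, matrix)``; ``top_k`` beyond the number of ROIs is
    clamped with a warning.
    """
    stats = np.asarray(stats, dtype=float)
    X = np.atleast_2d(dFF)
    if top_k > len(stats):
        import warnings

        warnings.warn(f"top_k={top_k} clamped to {len(stats)} ROIs", stacklevel=2)
        top_k = len(stats)
    order = np.lexsort((np.arange(len(stats)), -stats))[:top_k]
    return order, X[order]


def save_heatmap(
    matrix: np.ndarray,
    path: str | Path,
    side_flags: np.ndarray | None = None,
    title: str = "",
) -> None:
    """Render the ranked dF/F0 heatmap (plus spectral side columns) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if side_flags is not None and len(matrix):
        fig, (ax, axs) = plt.subplots(
            1, 2, figsize=(8, 6), width_ratios=[10, 1], sharey=True
        )
        axs.imshow(side_flags, aspect="auto", interpolation="nearest", cmap="Greys")
        axs.set_xticks(range(side_flags.shape[1]), CHANNELS, fontsize=6)
    else:
        fig, ax = plt.subplots(figsize=(8, 6))
    if len(matrix):
        ax.imshow(matrix, aspect="auto", interpolation="nearest", cmap="inferno")
    ax.set_xlabel("frame")
    ax.set_ylabel("ROI (ranked)")
    ax.set_title(title)
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Simulate-then-analyze round trip; returns a manifest dict.

    In ``traces`` mode the simulated per-neuron F traces feed the analysis
    directly (ROIs are the ground-truth neurons); in ``movie`` mode the
    cohort is rendered into per-plane stacks that are segmented and
    extracted before analysis.  A matched no-stimulus control of the same
    cohort supplies the empirical null for FDR thresholding.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    proto_cfg = config["protocol"]
    schedule = build_schedule(**proto_cfg)
    cirf_params = CirfParams(**config["cirf"])

    synth_cfg_all = dict(config["synth"])
    atlas_dims = tuple(synth_cfg_all.pop("atlas_dims"))
    mode = synth_cfg_all.pop("mode", "traces")
    bleed = float(synth_cfg_all.pop("bleed_through", 0.0))
    synth_cfg = SynthConfig(**synth_cfg_all, seed=seed)

    atlas = make_atlas(atlas_dims, seed=seed)
    truth = simulate_ground_truth(synth_cfg, atlas)
    truth_df = truth_manifest(truth)
    truth_df.to_csv(out / "truth.csv", index=False)
    stages["simulate"] = time.time() - t0
    log.info("simulated %d neurons (%d responders)", len(truth),
             int((truth_df["tbar"] > 0).sum()))

    sim_exp = simulate_traces(truth, schedule, cirf_params, synth_cfg)
    ctrl_cfg = SynthConfig(**synth_cfg_all, seed=seed + 1)
    sim_ctrl = simulate_traces(truth, None, cirf_params, ctrl_cfg,
                               frame_times_s=schedule.frame_times_s)

    seg_params = SegmentationParams(**config["segmentation"])
    if mode == "movie":
        t1 = time.time()
        H, Wd = atlas_dims[1], atlas_dims[2]
        stacks = render_movie(
            truth, sim_exp, (H, Wd), seed=seed, config=synth_cfg,
            schedule=schedule, bleed_through=bleed,
        )
        ctrl_stacks = render_movie(
            truth, sim_ctrl, (H, Wd), seed=seed + 1, config=synth_cfg,
        )
        rois, F_rows, Fc_rows = [], [], []
        offset = 0
        for z, stack in sorted(stacks.items()):
            tab = segment_plane(stack, z=z, params=seg_params, id_offset=offset)
            offset += len(tab)
            rois.append(tab)
            F_rows.append(extract_traces(stack, tab))
            Fc_rows.append(extract_traces(ctrl_stacks[z], tab))
        roi_df = pd.concat([t.to_frame() for t in rois], ignore_index=True)
        F = np.concatenate(F_rows) if F_rows else np.empty((0, schedule.n_frames))
        F_ctrl = np.concatenate(Fc_rows) if Fc_rows else F.copy()
        centroids = np.c_[roi_df["z"], roi_df["row"], roi_df["col"]]
        stages["segment"] = time.time() - t1
    else:
        roi_df = truth_df[["id", "z", "row", "col"]].rename(columns={"id": "roi_id"})
        roi_df = roi_df.assign(mip_intensity=np.nan)
        F = sim_exp.F
        F_ctrl = sim_ctrl.F
        centroids = np.c_[roi_df["z"], roi_df["row"], roi_df["col"]]
    roi_df.to_csv(out / "rois.csv", index=False)
    log.info("analyzing %d ROIs (%s mode)", len(roi_df), mode)

    t2 = time.time()
    base_cfg = config["baseline"]
    sm_cfg = config["smooth"]
    fp = proto_cfg["frame_period_s"]

    def process(Fmat: np.ndarray):
        cleaned, _ = remove_stimulus_frames(Fmat, schedule)
        F0 = estimate_baseline(cleaned, frame_period_s=fp, **base_cfg)
        return cleaned, smooth(compute_dff(cleaned, F0), frame_period_s=fp, **sm_cfg)

    F_clean, dff = process(F)
    _, dff_ctrl = process(F_ctrl)
    stages["traces"] = time.time() - t2

    t3 = time.time()
    from .selection import stimulus_frame_mask

    design = build_design_matrix(
        schedule, cirf_params, masked_frames=stimulus_frame_mask(schedule)
    )
    reg = regress_all(dff, design)
    reg_ctrl = regress_all(dff_ctrl, design)
    reg.to_frame(roi_df["roi_id"].to_numpy()).to_csv(out / "regression.csv", index=False)
    stages["regress"] = time.time() - t3

    t4 = time.time()
    sel_cfg = config["selection"]
    null_pool = symmetrize_control(reg_ctrl.T)
    thresholds = choose_thresholds(reg.T, null_pool, level=sel_cfg["level"])
    with open(out / "thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=2)
    sel = select_responders(
        reg.T, dff, schedule, thresholds, prominence=sel_cfg["prominence"],
        F=F_clean, design=design,
    )
    sel_df = sel.to_frame(roi_df["roi_id"].to_numpy())
    stages["select"] = time.time() - t4

    rep_cfg = config["report"]
    cls = class_summary(sel.tbar, dff, schedule, min_class_size=rep_cfg["min_class_size"])
    cls.to_csv(out / "class_summary.csv", index=False)

    regions = assign_regions(centroids, atlas)
    sel_df["region"] = regions
    sel_df["larva"] = 0
    sel_df.to_csv(out / "selection.csv", index=False)
    tal = tally(sel_df[sel_df["tbar"] > 0], group_by="tbar")
    tal.to_csv(out / "tally.csv", index=False)

    stat = reg.T4D if rep_cfg["ranking"] == "T4D" else reg.T[
        :, CHANNELS.index(rep_cfg["ranking"].removeprefix("T_"))
    ]
    order, mat = rank_heatmap(dff, stat, top_k=rep_cfg["top_k"])
    save_heatmap(
        mat, out / "heatmap.png",
        side_flags=sel.pass_channel[order].astype(float),
        title=f"top {len(order)} ROIs by {rep_cfg['ranking']}",
    )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "n_rois": int(len(roi_df)),
        "n_selected": int((sel.tbar > 0).sum()),
        "thresholds": thresholds,
        "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
        "table_hashes": {
            "truth": _hash_df(truth_df),
            "rois": _hash_df(roi_df),
            "selection": _hash_df(sel_df),
        },
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline done in %.1f s: %d/%d ROIs selected",
             time.time() - t0, manifest["n_selected"], manifest["n_rois"])
    return manifest
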