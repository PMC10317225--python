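"""End-to-end orchestration: simulate/read -> segment -> track -> traces -> fit -> compare.

`run_pipeline` executes both workflows on one paired time-lapse:

* new workflow: per-frame transmitted-light segmentation, Hungarian
  linking gated at one cell diameter, exclusion of incomplete tracks,
  per-frame contour integration of the fluorescence stack;
* original workflow: contours segmented once from the first fluorescence
  frame and frozen for the whole stack.

Every intermediate is persisted as a versioned CSV/TIFF next to a JSON
run log, and the two accepted rate-constant sets are compared with the
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import crrc.io as cio
from crrc import kinetics, popstats, segment, track as tracking, traces as tracing
from crrc.simulate import GroundTruth, ImageStack, SimulationConfig, SimulationResult, simulate_timelapse

logger = logging.getLogger("crrc")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "run_pipeline",
    "match_complete_tracks_to_truth",
    "match_static_contours_to_truth",
]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""


@dataclass
class PipelineConfig:
    """Everything one run needs; either a simulation config or input paths.

    Units: pixel_size um/px, gate_diameter_um um, t_start seconds,
    radius bounds um, alpha dimensionless.
    """

    simulation: SimulationConfig | None = None
    transmitted_tif: str | None = None
    fluorescence_tif: str | None = None
    timestamps_csv: str | None = None
    pixel_size: float = 0.65
    t_start: float = 0.0
    threshold_method: str = "otsu"
    threshold_params: dict = field(default_factory=dict)
    r_min_um: float = 3.0
    r_max_um: float = 12.0
    gate_diameter_um: float = 13.0
    ball_radius_px: int = 50
    alpha: float = 0.001
    bins: object = "fd"
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            missing = [
                name
                for name in ("transmitted_tif", "fluorescence_tif", "timestamps_csv")
                if getattr(self, name) is None
            ]
            if missing:
                raise PipelineError(f"input: no simulation config and missing paths: {missing}")
            for name in ("transmitted_tif", "fluorescence_tif", "timestamps_csv"):
                if not Path(getattr(self, name)).exists():
                    raise PipelineError(f"input: missing file {getattr(self, name)}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    transmitted: ImageStack
    fluorescence: ImageStack
    ground_truth: GroundTruth | None
    label_masks: np.ndarray
    detections: pd.DataFrame
    tracks_frame: pd.DataFrame
    motion_summary: pd.DataFrame
    static_detections: pd.DataFrame
    traces_new: pd.DataFrame
    traces_original: pd.DataFrame
    fits_new: pd.DataFrame
    fits_original: pd.DataFrame
    comparison: popstats.WorkflowComparison


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labeled with stage name
                raise PipelineError(f"{name}: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate/read")
def _acquire(config: PipelineConfig) -> tuple[ImageStack, ImageStack, GroundTruth | None]:
    if config.simulation is not None:
        sim_cfg = config.simulation
        if sim_cfg.rng_seed != config.seed:
            sim_cfg = dataclasses.replace(sim_cfg, rng_seed=config.seed)
        sim: SimulationResult = simulate_timelapse(sim_cfg)
        return sim.transmitted, sim.fluorescence, sim.ground_truth
    tl = cio.read_stack(config.transmitted_tif, config.timestamps_csv, "transmitted", config.pixel_size)
    fl = cio.read_stack(config.fluorescence_tif, config.timestamps_csv, "fluorescence", config.pixel_size)
    return tl, fl, None


@_stage("segment")
def _segment(config: PipelineConfig, tl: ImageStack) -> tuple[np.ndarray, pd.DataFrame]:
    return segment.segment_stack(
        tl.frames,
        tl.pixel_size,
        method=config.threshold_method,
        r_min=config.r_min_um,
        r_max=config.r_max_um,
        **config.threshold_params,
    )


@_stage("track")
def _track(
    config: PipelineConfig, detections: pd.DataFrame, tl: ImageStack
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n_frames = tl.n_frames
    per_frame = [
        detections[detections["frame"] == f].reset_index(drop=True) for f in range(n_frames)
    ]
    px = tl.pixel_size
    assignments = []
    for f in range(n_frames - 1):
        pos_a = per_frame[f][["row", "col"]].to_numpy() * px
        pos_b = per_frame[f + 1][["row", "col"]].to_numpy() * px
        assignments.append(tracking.link_frames(pos_a, pos_b, config.gate_diameter_um))
    tracks = tracking.build_tracks(assignments, [len(p) for p in per_frame])
    complete = tracking.filter_complete_tracks(tracks, n_frames)
    logger.info("track: %d tracks, %d complete", len(tracks), len(complete))
    tracks_frame = tracking.tracks_to_frame(complete, detections)
    speeds = []
    for tid, sub in tracks_frame.groupby("track_id"):
        sub = sub.sort_values("frame")
        v = tracking.track_speed(sub[["row", "col"]].to_numpy() * px, tl.timestamps[sub["frame"]])
        speeds.append({"track_id": tid, "speed_um_per_h": v})
    motion = pd.DataFrame(speeds, columns=["track_id", "speed_um_per_h"])
    return tracks_frame, motion


@_stage("traces")
def _traces(
    config: PipelineConfig,
    tracks_frame: pd.DataFrame,
    label_masks: np.ndarray,
    fl: ImageStack,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    fl_sub = np.stack(
        [tracing.subtract_background(f, config.ball_radius_px) for f in fl.frames]
    )
    traces_new = tracing.extract_traces_new(
        tracks_frame, label_masks, fl_sub, fl.timestamps, t_start=config.t_start
    )
    # original workflow: freeze contours segmented from the first fluorescence frame
    binary0 = segment.threshold_image(fl_sub[0], method=config.threshold_method, **config.threshold_params)
    labels0, det0 = segment.label_cells(binary0, fl.pixel_size, frame=0)
    det0 = segment.filter_by_radius(det0, config.r_min_um, config.r_max_um)
    traces_orig = tracing.extract_traces_static(
        labels0, det0["label"].to_numpy(), fl_sub, fl.timestamps, t_start=config.t_start
    )
    return traces_new, traces_orig, det0


@_stage("fit")
def _fit(traces: pd.DataFrame) -> pd.DataFrame:
    return kinetics.qc_filter(kinetics.fit_traces(traces))


@_stage("compare")
def _compare(config: PipelineConfig, fits_orig: pd.DataFrame, fits_new: pd.DataFrame):
    return popstats.compare_workflows(
        kinetics.accepted_k(fits_orig),
        kinetics.accepted_k(fits_new),
        alpha=config.alpha,
        bins=config.bins,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run both workflows end-to-end; persist intermediates if ``outdir`` given.

    Deterministic given (config, config.seed).
    """
    config.validate()
    tl, fl, gt = _acquire(config)
    label_masks, detections = _segment(config, tl)
    tracks_frame, motion = _track(config, detections, tl)
    traces_new, traces_orig, static_det = _traces(config, tracks_frame, label_masks, fl)
    fits_new = _fit(traces_new)
    fits_orig = _fit(traces_orig)
    comparison = _compare(config, fits_orig, fits_new)

    result = PipelineResult(
        config=config,
        transmitted=tl,
        fluorescence=fl,
        ground_truth=gt,
        label_masks=label_masks,
        detections=detections,
        tracks_frame=tracks_frame,
        motion_summary=motion,
        static_detections=static_det,
        traces_new=traces_new,
        traces_original=traces_orig,
        fits_new=fits_new,
        fits_original=fits_orig,
        comparison=comparison,
    )
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


@_stage("persist")
def _persist(result: PipelineResult, outdir: Path) -> None:
    import tifffile

    import crrc

    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_stack(result.transmitted, outdir / "transmitted.tif", outdir / "timestamps.csv")
    cio.write_stack(result.fluorescence, outdir / "fluorescence.tif", outdir / "timestamps.csv")
    tifffile.imwrite(outdir / "label_masks.tif", result.label_masks.astype(np.uint16), photometric="minisblack")
    cio.write_table(result.detections, outdir / "detections.csv")
    cio.write_table(result.tracks_frame, outdir / "tracks.csv")
    cio.write_table(result.motion_summary, outdir / "motion_summary.csv")
    cio.write_table(result.traces_new, outdir / "traces_new.csv")
    cio.write_table(result.traces_original, outdir / "traces_original.csv")
    cio.write_table(result.fits_new, outdir / "fits_new.csv")
    cio.write_table(result.fits_original, outdir / "fits_original.csv")
    if result.ground_truth is not None:
        from crrc.simulate import write_ground_truth

        write_ground_truth(result.ground_truth, outdir)
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(result.comparison.to_dict(), fh, indent=2)
    log = {
        "crrc_version": crrc.__version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": result.config.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(result.config).items()
            if k not in ("simulation",) and not isinstance(v, dict)
        },
        "simulated": result.ground_truth is not None,
        "n_detections": int(len(result.detections)),
        "n_complete_tracks": int(result.tracks_frame["track_id"].nunique()) if len(result.tracks_frame) else 0,
        "n_accepted_new": int(result.fits_new["accepted"].sum()) if len(result.fits_new) else 0,
        "n_accepted_original": int(result.fits_original["accepted"].sum()) if len(result.fits_original) else 0,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)


def match_complete_tracks_to_truth(
    result: PipelineResult, max_dist_um: float = 6.5
) -> pd.DataFrame:
    """Match each complete track (and each frozen first-frame contour) to its
    ground-truth cell by first-frame centroid distance.

    Returns a table (cell_id, true_k, track_id or None, static_label or None)
    used to score parameter recovery on simulations; requires a simulated run.
    """
    gt = result.ground_truth
    if gt is None:
        raise ValueError("ground truth only available for simulated runs")
    px = result.transmitted.pixel_size
    truth0 = gt.tracks[gt.tracks["frame"] == 0].sort_values("cell_id")
    true_pos = truth0[["row_um", "col_um"]].to_numpy()

    def nearest(points_um: np.ndarray) -> np.ndarray:
        """index of nearest ground-truth cell for each point, -1 if too far"""
        if len(points_um) == 0:
            return np.empty(0, dtype=int)
        d = np.hypot(
            points_um[:, None, 0] - true_pos[None, :, 0],
            points_um[:, None, 1] - true_pos[None, :, 1],
        )
        idx = np.argmin(d, axis=1)
        idx[d[np.arange(len(idx)), idx] > max_dist_um] = -1
        return idx

    rows = []
    t0 = result.tracks_frame[result.tracks_frame["frame"] == 0]
    match = nearest(t0[["row", "col"]].to_numpy() * px)
    for (_, rec), cell_idx in zip(t0.iterrows(), match):
        if cell_idx >= 0:
            rows.append(
                {
                    "cell_id": int(truth0.iloc[cell_idx]["cell_id"]),
                    "true_k": float(gt.cells.iloc[cell_idx]["k_per_min"]),
                    "track_id": int(rec["track_id"]),
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "true_k", "track_id"])


def match_static_contours_to_truth(result: PipelineResult, max_dist_um: float = 6.5) -> pd.DataFrame:
    """Match each frozen first-fluorescence-frame contour to its ground-truth cell.

    Returns (cell_id, true_k, static_label); simulation runs only.
    """
    gt = result.ground_truth
    if gt is None:
        raise ValueError("ground truth only available for simulated runs")
    px = result.fluorescence.pixel_size
    truth0 = gt.tracks[gt.tracks["frame"] == 0].sort_values("cell_id")
    true_pos = truth0[["row_fl_um", "col_fl_um"]].to_numpy()
    det = result.static_detections
    pts = det[["row", "col"]].to_numpy() * px
    rows = []
    for (_, rec), point in zip(det.iterrows(), pts):
        d = np.hypot(*(true_pos - point[None, :]).T)
        j = int(np.argmin(d))
        if d[j] <= max_dist_um:
            rows.append(
                {
                    "cell_id": int(truth0.iloc[j]["cell_id"]),
                    "true_k": float(gt.cells.iloc[j]["k_per_min"]),
                    "static_label": int(rec["label"]),
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "true_k", "static_label"])
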