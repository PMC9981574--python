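"""End-to-end orchestration: frames in, trajectories and statistics out.

The stage order follows the measurement chain: rolling-mean background
-> absolute difference -> 2-means binarization -> connected components
-> patch classification -> SORT tracking -> behaviour statistics.
Frames inside the background warm-up window produce no detections, so
all downstream outputs start when the buffer first fills.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import __version__, behavior
from .classify import ClassifierModel, classify_objects, features_from_patches, train_classifier
from .config import PipelineConfig, derive_seed
from .imaging import BackgroundModel, load_frames, subtract
from .motio import write_mot
from .segment import binarize, connected_components, kmeans_threshold
from .synthgen import SceneParams, generate_patch_db
from .track import AssociationParams, SortTracker, trajectories_to_mot

log = logging.getLogger("daphtrack")


@dataclasses.dataclass
class PipelineResult:
    trajectories: list
    start_frame: int
    n_frames: int
    per_frame_counts: list[dict]
    summary: dict


def default_classifier(config: PipelineConfig, scene: SceneParams | None = None) -> ClassifierModel:
    """Train the configured classifier on the synthetic patch database."""
    cc = config.classifier
    scene = scene or SceneParams(seed=derive_seed(config.seed, "scene"))
    patches, labels = generate_patch_db(
        scene, cc.n_train_per_class, seed=derive_seed(config.seed, "patch_db")
    )
    X = features_from_patches(patches, cc.feature_set)
    model = train_classifier(X, labels, method=cc.method, seed=derive_seed(config.seed, "classifier"))
    model.feature_set = cc.feature_set
    model.decision_threshold = cc.decision_threshold
    return model


def run_pipeline_frames(
    frames, config: PipelineConfig, classifier: ClassifierModel | None = None
) -> PipelineResult:
    """Run the full chain over in-memory grayscale frames."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames")
    h, w = frames[0].shape
    window = int(round(config.background.window_s * config.fps))
    if len(frames) < window + 1:
        raise ValueError(
            f"video has {len(frames)} frames but the background needs {window} to warm up"
        )
    if classifier is None:
        if config.classifier.model_path:
            from .classify import load_model

            classifier = load_model(config.classifier.model_path)
        else:
            classifier = default_classifier(config)

    bg = BackgroundModel(window, config.background.freeze_after_warmup)
    tc = config.tracker
    params = AssociationParams(
        lam=tc.lam,
        max_d=tc.max_d if tc.max_d is not None else 0.1 * float(np.hypot(w, h)),
        c_min=tc.c_min,
        max_age=tc.max_age,
        min_hits=tc.min_hits,
    )
    tracker = SortTracker(params)
    sc = config.segment
    start_frame = window
    counts = []

    for i, frame in enumerate(frames):
        if config.roi is not None:
            x, y, rw, rh = config.roi
            frame = frame[y : y + rh, x : x + rw]
        if bg.warmed_up:
            diff = subtract(frame, bg)
            thr = kmeans_threshold(
                diff, max_iter=sc.kmeans_max_iter, tol=sc.kmeans_tol, init=sc.kmeans_init,
                seed=derive_seed(config.seed, "kmeans"),
            )
            mask = binarize(diff, thr.threshold) if not thr.degenerate else np.zeros_like(diff, bool)
            objects = connected_components(mask, sc.min_area, frame_index=i)
            kept = classify_objects(classifier, frame, objects)
            tracker.step(i, [o for o, _ in kept])
            counts.append(
                {"frame": i, "candidates": len(objects), "daphnia": len(kept), "live_tracks": len(tracker.tracks)}
            )
            log.debug(
                "frame %d: %d candidates, %d classified daphnia, %d live tracks",
                i, len(objects), len(kept), len(tracker.tracks),
            )
        bg.update(frame)

    trajectories = tracker.trajectories
    bc = config.behavior
    summary = behavior.video_summary(trajectories, config.fps, bc.window_s, bc.epsilon)
    return PipelineResult(
        trajectories=trajectories,
        start_frame=start_frame,
        n_frames=len(frames),
        per_frame_counts=counts,
        summary=summary,
    )


def run_pipeline(config: PipelineConfig, frames=None, classifier=None) -> PipelineResult:
    """Run the chain and write all artifacts under ``config.out_dir``.

    Outputs: trajectories in MOT-Challenge CSV and tidy CSV, a per-video
    summary CSV, the per-interval behaviour table, and a run manifest
    (config + version + seed) sufficient to reproduce the run.
    """
    import pandas as pd
    import yaml

    if frames is None:
        if not config.input_path:
            raise ValueError("config.input_path is required when frames are not supplied")
        frames = load_frames(config.input_path)
    result = run_pipeline_frames(frames, config, classifier)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mot(trajectories_to_mot(result.trajectories), out / "trajectories_mot.csv")

    rows = [
        {
            "track_id": t.track_id,
            "frame": o.frame,
            "time_s": o.frame / config.fps,
            "u": o.centroid[0],
            "v": o.centroid[1],
            "w": o.bbox[2],
            "h": o.bbox[3],
        }
        for t in result.trajectories
        for o in t.observations
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "time_s", "u", "v", "w", "h"]).to_csv(
        out / "trajectories.csv", index=False
    )
    behavior.per_trajectory_table(result.trajectories, config.fps, config.behavior.interval_s).to_csv(
        out / "intervals.csv", index=False
    )
    pd.DataFrame([result.summary]).to_csv(out / "summary.csv", index=False)
    manifest = {"version": __version__, "config": config.to_dict()}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return result


def evaluate_run(gt_file, hyp_file, iou_match_threshold: float = 0.5):
    """Compare a ground-truth and a hypothesis MOT file.

    Frame ranges are intersected with a warning when they differ.
    Returns (TrackingMetrics, report DataFrame).
    """
    from .evaluate import evaluate_tracking, metrics_report
    from .motio import read_mot

    gt = read_mot(gt_file)
    hyp = read_mot(hyp_file)
    gt_frames = {r.frame for r in gt}
    hyp_frames = {r.frame for r in hyp}
    frames = None
    if gt and hyp and (min(gt_frames) != min(hyp_frames) or max(gt_frames) != max(hyp_frames)):
        lo = max(min(gt_frames), min(hyp_frames))
        hi = min(max(gt_frames), max(hyp_frames))
        log.warning("frame ranges differ; evaluating intersection [%d, %d]", lo, hi)
        frames = range(lo, hi + 1)
    metrics = evaluate_tracking(gt, hyp, iou_match_threshold, frames=frames)
    return metrics, metrics_report(metrics)
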