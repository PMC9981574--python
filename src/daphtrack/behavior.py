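"""Trajectory-level locomotory statistics.

The central quantity is the per-frame displacement: the Euclidean
distance between an animal's centroid in consecutive frames. From it
derive the per-trajectory average distance, per-20-s interval averages
(the unit analysed for concentration effects), the stationary filter
(animals motionless for >= 20 s are dropped as presumed immobile or
dead), the mobile count, and a radius of activity summarizing spatial
extent.

Distances are in pixels per frame; an optional mm-per-pixel scale can
be applied by the caller. Coasting gaps in a trajectory are by default
split across the missing frames so per-frame units stay comparable
(``gap_mode='skip'`` instead records the gap as a single displacement).
"""

from __future__ import annotations

import numpy as np


def frame_displacements(traj, gap_mode: str = "split") -> np.ndarray:
    """Euclidean distances between consecutive-frame centroids.

    A gap of g frames between observations contributes, in 'split' mode,
    g equal displacements of distance/g; in 'skip' mode one displacement
    of the full distance. Fewer than two observations yield an empty
    sequence.
    """
    obs = traj.observations if hasattr(traj, "observations") else list(traj)
    if len(obs) < 2:
        return np.array([])
    frames = np.array([o.frame if hasattr(o, "frame") else o[0] for o in obs])
    cents = np.array([o.centroid if hasattr(o, "centroid") else o[1] for o in obs], dtype=float)
    if np.any(np.diff(frames) <= 0):
        raise ValueError("trajectory frames must be strictly increasing")
    dists = np.hypot(*(cents[1:] - cents[:-1]).T)
    gaps = np.diff(frames)
    if gap_mode == "split":
        out: list[float] = []
        for d, g in zip(dists, gaps):
            out.extend([d / g] * int(g))
        return np.array(out)
    elif gap_mode == "skip":
        return dists
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def mean_se(values) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD / sqrt(n); 0 for n=1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_se requires at least one value")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def is_stationary(traj, fps: float, window_s: float = 20.0, epsilon: float = 0.5,
                  gap_mode: str = "split") -> bool:
    """True when the trajectory contains a run of >= window_s * fps
    consecutive per-frame displacements all <= epsilon."""
    run_len = int(round(window_s * fps))
    d = frame_displacements(traj, gap_mode=gap_mode)
    if d.size == 0:
        # a trajectory too short to move is treated as stationary only if
        # it spans the window; single observations cannot be judged
        return False
    run = 0
    for x in d:
        run = run + 1 if x <= epsilon else 0
        if run >= run_len:
            return True
    return False


def stationary_filter(trajs, fps: float, window_s: float = 20.0, epsilon: float = 0.5,
                      gap_mode: str = "split"):
    """Partition trajectories into (kept, removed) by the stationary rule."""
    kept, removed = [], []
    for t in trajs:
        (removed if is_stationary(t, fps, window_s, epsilon, gap_mode) else kept).append(t)
    return kept, removed


def mobile_count(trajs, fps: float, window_s: float = 20.0, epsilon: float = 0.5) -> int:
    """Number of trajectories that survive the stationary filter."""
    kept, _ = stationary_filter(trajs, fps, window_s, epsilon)
    return len(kept)


def interval_mean_distance(traj, fps: float, interval_s: float = 20.0,
                           gap_mode: str = "split") -> list[dict]:
    """Mean per-frame displacement per consecutive interval of
    interval_s seconds; the trailing partial interval is reported with
    its own frame count."""
    n_per = int(round(interval_s * fps))
    d = frame_displacements(traj, gap_mode=gap_mode)
    out = []
    for k in range(0, len(d), n_per):
        chunk = d[k : k + n_per]
        out.append(
            {"interval_index": k // n_per, "mean_distance": float(chunk.mean()), "n_frames": int(len(chunk))}
        )
    return out


def radius_of_activity(traj, method: str = "centroid") -> float:
    """Spatial extent of a trajectory.

    'centroid' (default): maximum distance from any visited point to the
    centroid of visited points. 'bounding_circle': half the diameter of
    the visited point set (an interpretation of the same idea; both are
    provided because the quantity has no standard definition).
    """
    obs = traj.observations if hasattr(traj, "observations") else list(traj)
    if len(obs) == 0:
        raise ValueError("radius_of_activity requires at least one observation")
    pts = np.array([o.centroid if hasattr(o, "centroid") else o[1] for o in obs], dtype=float)
    if method == "centroid":
        center = pts.mean(axis=0)
        return float(np.max(np.hypot(*(pts - center).T)))
    elif method == "bounding_circle":
        if len(pts) == 1:
            return 0.0
        from scipy.spatial.distance import pdist

        return float(pdist(pts).max() / 2.0)
    raise ValueError(f"unknown method {method!r}")


def video_summary(trajs, fps: float, window_s: float = 20.0, epsilon: float = 0.5) -> dict:
    """Video-level aggregation: mean and SE over per-trajectory mean
    displacements of the mobile animals, plus the mobile count."""
    kept, removed = stationary_filter(trajs, fps, window_s, epsilon)
    means = [float(frame_displacements(t).mean()) for t in kept if len(t.observations) >= 2]
    if means:
        m, se = mean_se(means)
    else:
        m, se = float("nan"), float("nan")
    return {
        "n_trajectories": len(list(trajs)),
        "mobile_count": len(kept),
        "stationary_count": len(removed),
        "mean_distance": m,
        "se_distance": se,
    }


def per_trajectory_table(trajs, fps: float, interval_s: float = 20.0):
    """Tidy per-interval table (track_id, interval_index, mean_distance,
    n_frames) ready for repeated-measures analysis."""
    import pandas as pd

    rows = []
    for t in trajs:
        if len(t.observations) < 2:
            continue
        for rec in interval_mean_distance(t, fps, interval_s):
            rows.append({"track_id": t.track_id, **rec})
    return pd.DataFrame(rows, columns=["track_id", "interval_index", "mean_distance", "n_frames"])
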