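"""SORT-style online multi-object tracking.

Each live track carries a constant-velocity Kalman state

    x = [u, v, s, r, du, dv, ds]

where (u, v) is the bounding-box centre, s its area (scale), r its
aspect ratio w/h (assumed constant), and du, dv, ds the per-frame
rates. Detections are associated to predicted tracks frame by frame by
maximizing the total of a mixed similarity

    C_ij = (1 - lambda) * max(0, (max_d - d_ij) / max_d) + lambda * IOU_ij

(d_ij = Euclidean centroid distance) under a one-to-one (Hungarian)
assignment; pairs below ``c_min`` are demoted to unmatched. Unmatched
detections spawn new tracks, tracks unmatched for more than ``max_age``
frames are terminated, and observations are emitted once a track has
accumulated ``min_hits`` matches (waived during the first ``min_hits``
frames so short videos are not truncated at the start).

Noise covariances follow the public SORT reference convention: large
initial uncertainty on the unobserved velocities, small measurement
noise on position, larger on scale/ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class AssociationParams:
    """Association and lifecycle parameters (none are given by a standard;
    all are surfaced in the pipeline config)."""

    lam: float = 0.5  # weight of the IOU term
    max_d: float = 58.0  # distance normalizer, px (default ~0.1 * 512x288 diagonal)
    c_min: float = 0.3  # minimum similarity for a valid match
    max_age: int = 5  # frames a track survives unmatched
    min_hits: int = 2  # matches before a track is emitted

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")
        if self.max_d <= 0:
            raise ValueError("max_d must be positive")
        if not (0.0 <= self.c_min <= 1.0):
            raise ValueError("c_min must be in [0, 1]")
        if self.max_age < 0 or self.min_hits < 1:
            raise ValueError("max_age >= 0 and min_hits >= 1 required")

    @staticmethod
    def for_frame(width: int, height: int, **overrides) -> "AssociationParams":
        """Defaults with max_d = 10 % of the frame diagonal."""
        d = float(np.hypot(width, height)) * 0.1
        return AssociationParams(**{"max_d": d, **overrides})


@dataclass
class Observation:
    frame: int
    bbox: tuple[float, float, float, float]
    centroid: tuple[float, float]


@dataclass
class Trajectory:
    """Identity-labelled sequence of per-frame boxes (gaps allowed)."""

    track_id: int
    observations: list[Observation] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [o.frame for o in self.observations]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([o.centroid for o in self.observations])

    def __len__(self) -> int:
        return len(self.observations)


# ---------------------------------------------------------------------------
# box geometry


def bbox_to_z(bbox) -> np.ndarray:
    """(x, y, w, h) -> measurement [u, v, s, r]."""
    x, y, w, h = (float(v) for v in bbox)
    return np.array([x + w / 2.0, y + h / 2.0, w * h, w / h if h > 0 else 1.0])


def z_to_bbox(z) -> tuple[float, float, float, float]:
    """[u, v, s, r] -> (x, y, w, h)."""
    u, v, s, r = (float(a) for a in z[:4])
    s = max(s, 1e-6)
    r = max(r, 1e-6)
    w = np.sqrt(s * r)
    h = s / w
    return (u - w / 2.0, v - h / 2.0, w, h)


def bbox_center(bbox) -> tuple[float, float]:
    x, y, w, h = (float(v) for v in bbox)
    return (x + w / 2.0, y + h / 2.0)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes; 0 for empty union."""
    ax, ay, aw, ah = (float(v) for v in box_a)
    bx, by, bw, bh = (float(v) for v in box_b)
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def association_cost(det_bbox, pred_bbox, params: AssociationParams) -> float:
    """Mixed similarity C_ij in [0, 1]: distance term clamped at zero so a
    detection farther than max_d contributes nothing, plus the IOU term."""
    du, dv = bbox_center(det_bbox)
    pu, pv = bbox_center(pred_bbox)
    d = float(np.hypot(du - pu, dv - pv))
    dist_term = max(0.0, (params.max_d - d) / params.max_d)
    return (1.0 - params.lam) * dist_term + params.lam * iou(det_bbox, pred_bbox)


def associate(similarity: np.ndarray, c_min: float):
    """Maximum-total-similarity one-to-one assignment with a validity gate.

    Returns (matches, unmatched_rows, unmatched_cols); assigned pairs with
    similarity < c_min are demoted to unmatched. Matches are sorted by row
    index (deterministic tie-breaking).
    """
    similarity = np.atleast_2d(np.asarray(similarity, dtype=np.float64))
    n_rows, n_cols = similarity.shape
    if similarity.size == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    rows, cols = linear_sum_assignment(-similarity)
    matches = []
    matched_r, matched_c = set(), set()
    for r, c in zip(rows, cols):
        if similarity[r, c] >= c_min:
            matches.append((int(r), int(c)))
            matched_r.add(int(r))
            matched_c.add(int(c))
    matches.sort()
    unmatched_rows = [r for r in range(n_rows) if r not in matched_r]
    unmatched_cols = [c for c in range(n_cols) if c not in matched_c]
    return matches, unmatched_rows, unmatched_cols


# ---------------------------------------------------------------------------
# Kalman filter (constant-velocity, SORT convention)

_F = np.eye(7)
_F[0, 4] = _F[1, 5] = _F[2, 6] = 1.0
_H = np.zeros((4, 7))
_H[0, 0] = _H[1, 1] = _H[2, 2] = _H[3, 3] = 1.0

_R = np.diag([1.0, 1.0, 10.0, 10.0])
_P0 = np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])
_Q = np.diag([1.0, 1.0, 1.0, 1.0, 0.01, 0.01, 1e-4])

_S_FLOOR = 1e-3


class TrackState:
    """Kalman state and lifecycle counters of one track."""

    def __init__(self, bbox, track_id: int, R=None, Q=None, P0=None):
        self.x = np.zeros(7)
        self.x[:4] = bbox_to_z(bbox)
        self.P = (_P0 if P0 is None else np.asarray(P0, dtype=np.float64)).copy()
        self.R = (_R if R is None else np.asarray(R, dtype=np.float64)).copy()
        self.Q = (_Q if Q is None else np.asarray(Q, dtype=np.float64)).copy()
        self.track_id = int(track_id)
        self.age = 0
        self.hits = 1
        self.time_since_update = 0
        self.last_bbox = tuple(float(v) for v in bbox)

    def predict(self) -> np.ndarray:
        """Constant-velocity propagation; returns the predicted [u,v,s,r]."""
        if self.x[2] + self.x[6] <= _S_FLOOR:
            self.x[6] = 0.0  # scale cannot shrink through zero
        self.x = _F @ self.x
        self.x[2] = max(self.x[2], _S_FLOOR)
        self.P = _F @ self.P @ _F.T + self.Q
        self.age += 1
        self.time_since_update += 1
        return self.x[:4].copy()

    def update(self, bbox) -> None:
        """Kalman measurement update with a detection box."""
        z = bbox_to_z(bbox)
        y = z - _H @ self.x
        S = _H @ self.P @ _H.T + self.R
        K = self.P @ _H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.x[2] = max(self.x[2], _S_FLOOR)
        self.x[3] = max(self.x[3], 1e-6)
        I_KH = np.eye(7) - K @ _H
        # Joseph form keeps P symmetric positive-definite
        self.P = I_KH @ self.P @ I_KH.T + K @ self.R @ K.T
        self.hits += 1
        self.time_since_update = 0
        self.last_bbox = tuple(float(v) for v in bbox)

    @property
    def predicted_bbox(self) -> tuple[float, float, float, float]:
        return z_to_bbox(self.x)


def kalman_predict(state: TrackState) -> TrackState:
    """Functional wrapper used by tests: predict in place and return the state."""
    state.predict()
    return state


# ---------------------------------------------------------------------------
# tracker


class SortTracker:
    """Online tracker: call :meth:`step` once per frame in order."""

    def __init__(self, params: AssociationParams | None = None, kalman_noise: dict | None = None):
        self.params = params or AssociationParams()
        self.kalman_noise = kalman_noise or {}
        self.tracks: list[TrackState] = []
        self._next_id = 1
        self._frame_count = 0
        self._trajectories: dict[int, Trajectory] = {}

    def step(self, frame_index: int, detections) -> list[tuple[int, Observation]]:
        """Advance one frame.

        ``detections`` is a sequence of (x, y, w, h) boxes (CandidateObject
        bboxes work directly). Returns the (track_id, observation) pairs
        emitted for this frame and accumulates them into trajectories.
        """
        self._frame_count += 1
        det_boxes = [tuple(float(v) for v in (d.bbox if hasattr(d, "bbox") else d)) for d in detections]

        for t in self.tracks:
            t.predict()

        sim = np.zeros((len(det_boxes), len(self.tracks)))
        for i, db in enumerate(det_boxes):
            for j, t in enumerate(self.tracks):
                sim[i, j] = association_cost(db, t.predicted_bbox, self.params)
        matches, unmatched_dets, _ = associate(sim, self.params.c_min)

        for di, tj in matches:
            self.tracks[tj].update(det_boxes[di])
        for di in unmatched_dets:
            t = TrackState(det_boxes[di], self._next_id, **self.kalman_noise)
            self._next_id += 1
            self.tracks.append(t)

        emitted: list[tuple[int, Observation]] = []
        for t in self.tracks:
            if t.time_since_update == 0 and (
                t.hits >= self.params.min_hits or self._frame_count <= self.params.min_hits
            ):
                obs = Observation(frame_index, t.last_bbox, bbox_center(t.last_bbox))
                traj = self._trajectories.setdefault(t.track_id, Trajectory(t.track_id))
                traj.observations.append(obs)
                emitted.append((t.track_id, obs))

        self.tracks = [t for t in self.tracks if t.time_since_update <= self.params.max_age]
        return emitted

    @property
    def trajectories(self) -> list[Trajectory]:
        return [self._trajectories[k] for k in sorted(self._trajectories)]


def track_video(detections_by_frame, params: AssociationParams | None = None) -> list[Trajectory]:
    """Run the tracker over a whole video.

    ``detections_by_frame`` is either a dict {frame_index: [bboxes]} or a
    list indexed by frame. Frames are processed in increasing order;
    deterministic given its inputs.
    """
    tracker = SortTracker(params)
    if isinstance(detections_by_frame, dict):
        frames = sorted(detections_by_frame)
        items = [(f, detections_by_frame[f]) for f in frames]
    else:
        items = list(enumerate(detections_by_frame))
    for f, dets in items:
        tracker.step(f, dets)
    return tracker.trajectories


def trajectories_to_mot(trajectories) -> list:
    """Flatten trajectories to MOT records sorted by (frame, id)."""
    from .motio import MotRecord

    recs = [
        MotRecord(o.frame, t.track_id, tuple(o.bbox))
        for t in trajectories
        for o in t.observations
    ]
    recs.sort(key=lambda r: (r.frame, r.track_id))
    return recs
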