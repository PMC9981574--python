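"""Kalman prediction, association and tracker lifecycle."""

import numpy as np
import pytest

from daphtrack import AssociationParams, SortTracker, associate, association_cost, iou, track_video
from daphtrack.evaluate import evaluate_tracking
from daphtrack.track import TrackState, bbox_to_z, kalman_predict, z_to_bbox

from .oracles import best_assignment_total


# ---------------------------------------------------------------------------
# Kalman


def test_zero_velocity_leaves_position():
    t = TrackState((10, 20, 4, 4), track_id=1)
    t.predict()
    u, v = t.x[0], t.x[1]
    assert (u, v) == (12.0, 22.0)  # bbox centre of (10,20,4,4)


def test_velocity_advances_position():
    t = TrackState((8, 0, 4, 4), track_id=1)
    t.x[4] = 2.0  # du
    kalman_predict(t)
    assert t.x[0] == 12.0  # centre 10 + 2


def test_k_step_constant_velocity_closed_form():
    t = TrackState((0, 0, 9, 1), track_id=1)
    u0 = t.x[0]
    t.x[4], t.x[5] = 1.5, -0.5
    for _ in range(7):
        t.predict()
    assert t.x[0] == pytest.approx(u0 + 7 * 1.5)
    assert t.x[1] == pytest.approx(t.x[5] * 7 + 0.5)  # v0 was 0.5


def test_exact_measurement_with_zero_noise_reproduces_measurement():
    t = TrackState((5, 5, 6, 4), track_id=1, R=np.zeros((4, 4)))
    t.predict()
    target = (30.0, 40.0, 8.0, 6.0)
    t.update(target)
    np.testing.assert_allclose(t.x[:4], bbox_to_z(target), atol=1e-9)


def test_covariance_stays_symmetric_positive_definite(rng):
    t = TrackState((0, 0, 5, 5), track_id=1)
    for _ in range(25):
        t.predict()
        t.update(tuple(rng.uniform(0, 50, 2)) + (5.0, 5.0))
        np.testing.assert_allclose(t.P, t.P.T, atol=1e-9)
        assert np.all(np.linalg.eigvalsh(t.P) > 0)


def test_bbox_z_round_trip():
    bbox = (3.0, 7.0, 10.0, 4.0)
    np.testing.assert_allclose(z_to_bbox(bbox_to_z(bbox)), bbox, atol=1e-9)


# ---------------------------------------------------------------------------
# IOU and association cost


def test_iou_examples():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert iou((0, 0, 2, 2), (10, 10, 2, 2)) == 0.0
    assert iou((0, 0, 2, 2), (1, 0, 2, 2)) == pytest.approx(1 / 3)
    assert iou((0, 0, 0, 0), (0, 0, 0, 0)) == 0.0


def test_association_cost_lambda_extremes():
    p1 = AssociationParams(lam=1.0, max_d=100.0)
    a, b = (0, 0, 2, 2), (1, 0, 2, 2)
    assert association_cost(a, b, p1) == pytest.approx(iou(a, b))
    p0 = AssociationParams(lam=0.0, max_d=100.0)
    assert association_cost(a, a, p0) == 1.0


def test_association_cost_mixed_value():
    # lam=0.5, d = max_d/2, IOU = 0.5 -> 0.5*0.5 + 0.5*0.5 = 0.5
    params = AssociationParams(lam=0.5, max_d=8.0)
    det = (0.0, 0.0, 4.0, 4.0)
    pred = (0.0, 4.0, 4.0, 4.0)  # centres 4 px apart vertically, IOU = 0 though
    d = 4.0
    expected = 0.5 * (8.0 - d) / 8.0 + 0.5 * iou(det, pred)
    assert association_cost(det, pred, params) == pytest.approx(expected)


def test_association_cost_clamped_beyond_max_d():
    params = AssociationParams(lam=0.25, max_d=5.0)
    det = (0, 0, 2, 2)
    pred = (100, 100, 2, 2)
    assert association_cost(det, pred, params) == 0.0  # no negative distance term


def test_association_cost_in_unit_interval(rng):
    params = AssociationParams(lam=0.4, max_d=20.0)
    for _ in range(100):
        det = tuple(rng.uniform(0, 50, 2)) + tuple(rng.uniform(1, 10, 2))
        pred = tuple(rng.uniform(0, 50, 2)) + tuple(rng.uniform(1, 10, 2))
        c = association_cost(det, pred, params)
        assert 0.0 <= c <= 1.0


# ---------------------------------------------------------------------------
# assignment


def test_two_by_two_assignment():
    matches, ur, uc = associate(np.array([[0.9, 0.1], [0.2, 0.8]]), c_min=0.0)
    assert matches == [(0, 0), (1, 1)]
    assert ur == [] and uc == []


def test_threshold_demotes_weak_pairs():
    sim = np.array([[0.96, 0.2], [0.2, 0.3]])
    matches, ur, uc = associate(sim, c_min=0.95)
    assert matches == [(0, 0)]  # (1, 1) is optimally assigned but below c_min
    assert ur == [1] and uc == [1]


def test_empty_matrix_all_unmatched():
    matches, ur, uc = associate(np.zeros((0, 3)), c_min=0.5)
    assert matches == [] and ur == [] and uc == [0, 1, 2]


def test_assignment_total_matches_enumeration(rng):
    for _ in range(60):
        n, m = rng.integers(1, 7, 2)
        S = rng.random((n, m))
        matches, _, _ = associate(S, c_min=0.0)
        total = sum(S[r, c] for r, c in matches)
        assert total == pytest.approx(best_assignment_total(S))


# ---------------------------------------------------------------------------
# tracker lifecycle


def test_step_with_nothing_is_noop():
    tracker = SortTracker()
    assert tracker.step(0, []) == []
    assert tracker.tracks == []


def test_match_resets_time_since_update():
    tracker = SortTracker(AssociationParams(max_d=50))
    tracker.step(0, [(10, 10, 5, 5)])
    tracker.step(1, [(11, 10, 5, 5)])
    assert len(tracker.tracks) == 1
    assert tracker.tracks[0].time_since_update == 0
    assert tracker.tracks[0].hits == 2


def test_stationary_detection_yields_one_full_trajectory():
    dets = {f: [(20, 20, 6, 6)] for f in range(100)}
    trajs = track_video(dets, AssociationParams(max_d=50))
    assert len(trajs) == 1
    # emission waives min_hits during the first frames, so all 100 appear
    assert len(trajs[0]) == 100
    assert trajs[0].frames == list(range(100))


def test_long_gap_spawns_new_identity():
    dets = {f: [(20, 20, 6, 6)] for f in range(10)}
    dets.update({f: [] for f in range(10, 20)})  # gap > max_age
    dets.update({f: [(20, 20, 6, 6)] for f in range(20, 30)})
    trajs = track_video(dets, AssociationParams(max_d=50, max_age=5))
    assert len(trajs) == 2
    assert trajs[0].track_id != trajs[1].track_id


def test_track_ids_never_reused(rng):
    tracker = SortTracker(AssociationParams(max_d=10, max_age=0, min_hits=1))
    seen = set()
    for f in range(30):
        dets = [tuple(rng.uniform(0, 200, 2)) + (5.0, 5.0) for _ in range(rng.integers(0, 4))]
        tracker.step(f, dets)
        ids = [t.track_id for t in tracker.tracks]
        assert len(ids) == len(set(ids))
        seen.update(ids)
    assert max(seen, default=0) <= tracker._next_id - 1


def test_crossing_targets_keep_identities():
    # two boxes crossing with clearly distinct velocities: the motion model
    # must carry identities through the crossing
    n = 41
    dets = {}
    for f in range(n):
        a = (2.0 * f, 50.0, 8.0, 8.0)          # left -> right
        b = (80.0 - 2.0 * f, 58.0, 8.0, 8.0)   # right -> left, offset row
        dets[f] = [a, b]
    params = AssociationParams(lam=0.5, max_d=30.0, c_min=0.1, min_hits=1)
    trajs = track_video(dets, params)
    gt = [
        type("R", (), {"frame": f, "track_id": tid, "bbox": box})()
        for f in range(n)
        for tid, box in ((1, (2.0 * f, 50.0, 8.0, 8.0)), (2, (80.0 - 2.0 * f, 58.0, 8.0, 8.0)))
    ]
    m = evaluate_tracking(gt, trajs)
    assert m.id_switches == 0
    assert m.mota == 100.0


def test_perfect_detections_give_perfect_tracking(small_scene, small_scene_params):
    _, gt = small_scene
    by_frame = {}
    for r in gt.records:
        by_frame.setdefault(r.frame, []).append(r.bbox)
    params = AssociationParams.for_frame(small_scene_params.width, small_scene_params.height)
    trajs = track_video(by_frame, params)
    m = evaluate_tracking(gt, trajs)
    assert m.mota == 100.0 and m.id_switches == 0
    assert len(trajs) == small_scene_params.n_daphnia
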