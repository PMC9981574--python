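"""Tracking evaluation: CLEAR MOT and identity metrics.

CLEAR MOT performs per-frame matching between ground-truth and
hypothesis boxes: correspondences from the previous frame are kept
while their IOU stays at or above the gate, and the remaining boxes are
matched by a maximum-total-IOU assignment (gated). From the match
sequence:

    MOTA = 100 * (1 - (FN + FP + IDs) / num_gt_boxes)
    MOTP = 100 * mean IOU over matched pairs
    IDs  = number of events where a ground-truth track's matched
           hypothesis identity changes

The identity metrics (IDP/IDR/IDF1) instead match *whole trajectories*
one-to-one, minimizing the total number of frame-level identity errors;
IDTP is the number of frames covered by the optimal pairing,
IDFN/IDFP the uncovered ground-truth/hypothesis frames, and

    IDP = 100 * IDTP / (IDTP + IDFP)
    IDR = 100 * IDTP / (IDTP + IDFN)
    IDF1 = 100 * 2 * IDTP / (2 * IDTP + IDFP + IDFN)

All percentages follow the reporting convention of the MOT-Challenge
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .motio import MotRecord
from .track import iou

IOU_GATE_DEFAULT = 0.5


@dataclass(frozen=True)
class TrackingMetrics:
    """The Table-style metric set; percentages in [0, 100] except MOTA,
    which can go negative when errors exceed ground-truth boxes."""

    mota: float | None
    motp: float | None
    id_switches: int
    idp: float | None
    idr: float | None
    idf1: float | None
    fp: int
    fn: int
    matches: int
    idtp: int
    idfp: int
    idfn: int
    num_gt: int

    def as_row(self) -> dict:
        return {
            "IDF1": self.idf1,
            "IDP": self.idp,
            "IDR": self.idr,
            "IDs": self.id_switches,
            "MOTA": self.mota,
            "MOTP": self.motp,
        }


def _normalize(records) -> dict[int, dict[int, tuple[float, float, float, float]]]:
    """Accept MotRecords, GTRecords, or trajectories; return
    {frame: {track_id: bbox}}."""
    recs: list = []
    if hasattr(records, "records"):  # GroundTruth
        records = records.records
    for item in records:
        if hasattr(item, "observations"):  # Trajectory
            for o in item.observations:
                recs.append((o.frame, item.track_id, o.bbox))
        elif isinstance(item, (MotRecord, tuple)) or hasattr(item, "bbox"):
            frame = item.frame if hasattr(item, "frame") else item[0]
            tid = item.track_id if hasattr(item, "track_id") else item[1]
            bbox = item.bbox if hasattr(item, "bbox") else item[2]
            recs.append((int(frame), int(tid), tuple(float(v) for v in bbox)))
        else:
            raise TypeError(f"unsupported record {item!r}")
    out: dict[int, dict[int, tuple]] = {}
    for frame, tid, bbox in recs:
        out.setdefault(frame, {})[tid] = bbox
    return out


def clear_mot(gt, hyp, iou_match_threshold: float = IOU_GATE_DEFAULT, frames=None):
    """CLEAR MOT events and scores; see module docstring for definitions.

    ``frames`` restricts evaluation to a frame subset (e.g. frames after
    background warm-up). Empty ground truth leaves MOTA undefined (None).
    """
    G = _normalize(gt)
    H = _normalize(hyp)
    if frames is None:
        frame_list = sorted(set(G) | set(H))
    else:
        frame_list = sorted(frames)

    fp = fn = n_matches = switches = 0
    num_gt = 0
    iou_sum = 0.0
    last_match: dict[int, int] = {}  # gt id -> last matched hyp id (persists through gaps)
    prev_pairs: dict[int, int] = {}  # gt id -> hyp id matched in the previous frame

    for f in frame_list:
        gboxes = G.get(f, {})
        hboxes = H.get(f, {})
        num_gt += len(gboxes)
        pairs: dict[int, int] = {}

        # carry over previous-frame correspondences that still overlap
        for gid, hid in prev_pairs.items():
            if gid in gboxes and hid in hboxes and hid not in pairs.values():
                ov = iou(gboxes[gid], hboxes[hid])
                if ov >= iou_match_threshold:
                    pairs[gid] = hid
                    iou_sum += ov
                    n_matches += 1

        free_g = [g for g in sorted(gboxes) if g not in pairs]
        free_h = [h for h in sorted(hboxes) if h not in pairs.values()]
        if free_g and free_h:
            M = np.array([[iou(gboxes[g], hboxes[h]) for h in free_h] for g in free_g])
            rows, cols = linear_sum_assignment(-M)
            for r, c in zip(rows, cols):
                if M[r, c] >= iou_match_threshold:
                    pairs[free_g[r]] = free_h[c]
                    iou_sum += M[r, c]
                    n_matches += 1

        for gid, hid in pairs.items():
            if gid in last_match and last_match[gid] != hid:
                switches += 1
            last_match[gid] = hid

        fn += len(gboxes) - len(pairs)
        fp += len(hboxes) - len(pairs)
        prev_pairs = pairs

    mota = 100.0 * (1.0 - (fn + fp + switches) / num_gt) if num_gt else None
    motp = 100.0 * iou_sum / n_matches if n_matches else None
    return {
        "mota": mota,
        "motp": motp,
        "id_switches": switches,
        "fp": fp,
        "fn": fn,
        "matches": n_matches,
        "num_gt": num_gt,
    }


def id_metrics(gt, hyp, iou_match_threshold: float = IOU_GATE_DEFAULT, frames=None):
    """Identity precision/recall/F1 under optimal whole-trajectory matching."""
    G = _normalize(gt)
    H = _normalize(hyp)
    if frames is not None:
        keep = set(frames)
        G = {f: v for f, v in G.items() if f in keep}
        H = {f: v for f, v in H.items() if f in keep}

    # per-trajectory frame->bbox views
    gtraj: dict[int, dict[int, tuple]] = {}
    htraj: dict[int, dict[int, tuple]] = {}
    for f, boxes in G.items():
        for tid, b in boxes.items():
            gtraj.setdefault(tid, {})[f] = b
    for f, boxes in H.items():
        for tid, b in boxes.items():
            htraj.setdefault(tid, {})[f] = b

    gids, hids = sorted(gtraj), sorted(htraj)
    n_g, n_h = len(gids), len(hids)
    total_g = sum(len(v) for v in gtraj.values())
    total_h = sum(len(v) for v in htraj.values())

    def overlap(gd, hd) -> int:
        return sum(
            1 for f in gd.keys() & hd.keys() if iou(gd[f], hd[f]) >= iou_match_threshold
        )

    # square cost matrix with dummy rows/cols: pairing with a dummy costs the
    # trajectory's full length (all frames become misses / false positives)
    size = n_g + n_h
    idtp = 0
    if size:
        cost = np.zeros((size, size))
        for i, gid in enumerate(gids):
            cost[i, n_h:] = len(gtraj[gid])
        for j, hid in enumerate(hids):
            cost[n_g:, j] = len(htraj[hid])
        match_counts = np.zeros((n_g, n_h), dtype=int)
        for i, gid in enumerate(gids):
            for j, hid in enumerate(hids):
                m = overlap(gtraj[gid], htraj[hid])
                match_counts[i, j] = m
                cost[i, j] = (len(gtraj[gid]) - m) + (len(htraj[hid]) - m)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if r < n_g and c < n_h:
                idtp += int(match_counts[r, c])

    idfn = total_g - idtp
    idfp = total_h - idtp
    idp = 100.0 * idtp / (idtp + idfp) if (idtp + idfp) else None
    idr = 100.0 * idtp / (idtp + idfn) if (idtp + idfn) else None
    idf1 = 100.0 * 2 * idtp / (2 * idtp + idfp + idfn) if (2 * idtp + idfp + idfn) else None
    return {"idp": idp, "idr": idr, "idf1": idf1, "idtp": idtp, "idfp": idfp, "idfn": idfn}


def evaluate_tracking(gt, hyp, iou_match_threshold: float = IOU_GATE_DEFAULT, frames=None) -> TrackingMetrics:
    """Full metric set (CLEAR MOT + identity) for one video."""
    c = clear_mot(gt, hyp, iou_match_threshold, frames=frames)
    i = id_metrics(gt, hyp, iou_match_threshold, frames=frames)
    return TrackingMetrics(
        mota=c["mota"],
        motp=c["motp"],
        id_switches=c["id_switches"],
        idp=i["idp"],
        idr=i["idr"],
        idf1=i["idf1"],
        fp=c["fp"],
        fn=c["fn"],
        matches=c["matches"],
        idtp=i["idtp"],
        idfp=i["idfp"],
        idfn=i["idfn"],
        num_gt=c["num_gt"],
    )


def metrics_report(metrics: TrackingMetrics, method: str = "ours"):
    """One-row report with the standard comparison columns."""
    import pandas as pd

    row = {"Method": method, **metrics.as_row()}
    return pd.DataFrame([row], columns=["Method", "IDF1", "IDP", "IDR", "IDs", "MOTA", "MOTP"])
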