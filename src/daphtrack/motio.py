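"""MOT-Challenge CSV input/output.

The de facto interchange format for multi-object tracking annotations is a
headerless CSV with one box per line::

    frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z

Frame numbers and track ids are 1-based in the file; the in-memory
convention throughout this package is 0-based frame indices, so reading
and writing shift the frame index by one. Ground-truth files carry
``conf = 1``; the trailing world-coordinate fields are unused and
written as ``-1``.
"""

from __future__ import annotations

import os
from typing import Iterable, NamedTuple, Sequence


class MotRecord(NamedTuple):
    """One annotated box: 0-based frame, positive track id, (x, y, w, h) box."""

    frame: int
    track_id: int
    bbox: tuple[float, float, float, float]
    conf: float = 1.0


def _coerce(rec) -> MotRecord:
    if isinstance(rec, MotRecord):
        return rec
    # duck-typed: synthgen.GTRecord and track.Trajectory observations
    if hasattr(rec, "frame") and hasattr(rec, "track_id") and hasattr(rec, "bbox"):
        return MotRecord(int(rec.frame), int(rec.track_id), tuple(float(v) for v in rec.bbox))
    frame, track_id, *rest = rec
    if len(rest) == 1:
        bbox, conf = rest[0], 1.0
    elif len(rest) == 2:
        bbox, conf = rest
    elif len(rest) == 4:
        bbox, conf = rest, 1.0
    else:
        bbox, conf = rest[:4], rest[4]
    return MotRecord(int(frame), int(track_id), tuple(float(v) for v in bbox), float(conf))


def _fmt(v: float) -> str:
    # integers print without a trailing ".0"; floats print with full
    # round-trip precision so read(write(x)) == x holds exactly
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_mot(records: Iterable, destination: str | os.PathLike) -> None:
    """Write records as MOT-Challenge CSV (frame and id 1-based in the file)."""
    lines = []
    for rec in records:
        r = _coerce(rec)
        x, y, w, h = r.bbox
        lines.append(
            ",".join(
                [str(r.frame + 1), str(r.track_id), _fmt(x), _fmt(y), _fmt(w), _fmt(h), _fmt(r.conf), "-1", "-1", "-1"]
            )
        )
    with open(destination, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def read_mot(source: str | os.PathLike) -> list[MotRecord]:
    """Read a MOT-Challenge CSV; frame indices are returned 0-based.

    Raises
    ------
    ValueError
        On a malformed line, naming the 1-based line number.
    """
    records: list[MotRecord] = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 6:
                raise ValueError(f"malformed MOT line {lineno}: expected >= 6 fields, got {len(parts)}")
            try:
                frame = int(float(parts[0])) - 1
                track_id = int(float(parts[1]))
                bbox = tuple(float(p) for p in parts[2:6])
                conf = float(parts[6]) if len(parts) > 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"malformed MOT line {lineno}: {exc}") from None
            if frame < 0:
                raise ValueError(f"malformed MOT line {lineno}: frame must be >= 1 in file")
            records.append(MotRecord(frame, track_id, bbox, conf))
    return records


def records_by_frame(records: Sequence[MotRecord]) -> dict[int, list[MotRecord]]:
    """Group records into {frame_index: [records]} preserving order."""
    out: dict[int, list[MotRecord]] = {}
    for r in records:
        out.setdefault(r.frame, []).append(r)
    return out
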