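"""Seeded synthetic flow-cell scenes with ground truth.

Emulates the imaging situation of a backlit Daphnia flow cell: dark
elliptical swimmers on a light background, photographed at 15 fps,
plus the nuisance objects a real cell accumulates — static droplets
stuck to the glass and sediment particles drifting slowly with the
flow. Every run is fully determined by the scene seed, and the
generator emits per-frame ground-truth boxes for the animals only, so
detection, tracking and evaluation can all be exercised without real
video.

Animal motion is a persistent random walk (velocity relaxes toward its
previous direction with Gaussian perturbations) with reflective walls —
deliberately *not* the constant-velocity model the tracker assumes, so
tracking tests are not self-fulfilling. A weak short-range avoidance
between animals keeps silhouettes disjoint: real daphnia avoid contact,
and splitting merged silhouettes is outside the scope of the
segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .classify import PATCH_SIZE, area_average_resize
from .motio import read_mot, write_mot  # re-exported: MOT files are this module's on-disk form

__all__ = [
    "SceneParams",
    "GTRecord",
    "GroundTruth",
    "generate_video",
    "generate_patch_db",
    "write_mot",
    "read_mot",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    Defaults model a quarter-scale view of the 2048x1088 @ 15 fps flow-cell
    camera: animals span ~6-12 px (2-4 % of the frame width), swim at
    ~1 px/frame rms, and appear dark (fg 60) on a bright backlit field
    (bg 200) with mild sensor noise.
    """

    width: int = 512
    height: int = 288
    n_frames: int = 450
    fps: float = 15.0
    n_daphnia: int = 5
    n_noise_static: int = 3
    n_noise_drift: int = 2
    blob_axis_range: tuple[float, float] = (3.0, 6.0)
    speed_sigma: float = 0.5
    velocity_persistence: float = 0.85
    bg_level: float = 200.0
    fg_level: float = 60.0
    pixel_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height, self.n_frames) < 1:
            raise ValueError("width, height and n_frames must be >= 1")
        if not (0 <= self.fg_level <= 255 and 0 <= self.bg_level <= 255):
            raise ValueError("intensity levels must lie in [0, 255]")
        if self.fg_level == self.bg_level:
            raise ValueError("fg_level must differ from bg_level")
        if not (0.0 <= self.velocity_persistence <= 1.0):
            raise ValueError("velocity_persistence must be in [0, 1]")
        a_lo, a_hi = self.blob_axis_range
        if not (0 < a_lo <= a_hi):
            raise ValueError("blob_axis_range must be positive and ordered")
        if 2 * a_hi >= min(self.width, self.height):
            raise ValueError("blob axes exceed frame size")


class GTRecord(NamedTuple):
    """Ground-truth box of one animal in one frame (0-based frame index)."""

    frame: int
    track_id: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]


@dataclass
class GroundTruth:
    """All ground-truth records of a scene; at most one per (frame, id)."""

    records: list[GTRecord] = field(default_factory=list)

    def by_frame(self) -> dict[int, list[GTRecord]]:
        out: dict[int, list[GTRecord]] = {}
        for r in self.records:
            out.setdefault(r.frame, []).append(r)
        return out

    def for_track(self, track_id: int) -> list[GTRecord]:
        return [r for r in self.records if r.track_id == track_id]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# rendering helpers


def _stamp_ellipse(img, cy, cx, a, b, theta, level, soften=0.35):
    """Paint an ellipse, shading toward the rim so the body has texture.

    Works on a local window for speed; returns (local silhouette mask,
    y-offset, x-offset) of that window within the frame.
    """
    h, w = img.shape
    R = max(a, b) + 1.0
    y0 = max(int(np.floor(cy - R)), 0)
    y1 = min(int(np.ceil(cy + R)) + 1, h)
    x0 = max(int(np.floor(cx - R)), 0)
    x1 = min(int(np.ceil(cx + R)) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return np.zeros((0, 0), dtype=bool), y0, x0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    rho2 = ((dx * ct + dy * st) / a) ** 2 + ((-dx * st + dy * ct) / b) ** 2
    mask = rho2 <= 1.0
    if mask.any():
        window = img[y0:y1, x0:x1]
        window[mask] = level + (window[mask] - level) * soften * rho2[mask]
    return mask, y0, x0


def _tight_bbox(mask: np.ndarray, y_off: int = 0, x_off: int = 0) -> tuple[int, int, int, int] | None:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    y0, y1 = rows.min() + y_off, rows.max() + y_off
    x0, x1 = cols.min() + x_off, cols.max() + x_off
    return int(x0), int(y0), int(x1 - x0 + 1), int(y1 - y0 + 1)


def _mass_center(mask: np.ndarray, y_off: int = 0, x_off: int = 0) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(cols.mean() + x_off), float(rows.mean() + y_off)


# ---------------------------------------------------------------------------
# scene state


class _Swimmer:
    def __init__(self, pos, vel, axes, theta):
        self.pos = np.asarray(pos, dtype=np.float64)
        self.vel = np.asarray(vel, dtype=np.float64)
        self.axes = axes  # (a, b) semi-axes, a >= b
        self.theta = theta


def _init_positions(rng, n, width, height, margin, min_sep):
    """Rejection-sample n well-separated start positions."""
    pts: list[np.ndarray] = []
    for _ in range(10_000):
        if len(pts) == n:
            break
        cand = rng.uniform([margin, margin], [width - 1 - margin, height - 1 - margin])
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
    if len(pts) < n:
        raise ValueError("could not place animals with the requested separation; frame too small")
    return pts


def generate_video(params: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene; returns (frames uint8 (n, h, w), GroundTruth).

    Ground truth covers every animal in every frame (tight silhouette
    bbox + silhouette mass centre); noise objects are excluded.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    a_lo, a_hi = p.blob_axis_range
    margin = a_hi + 2.0

    # --- daphnia ---
    sep = 4.0 * a_hi
    swimmers: list[_Swimmer] = []
    if p.n_daphnia > 0:
        positions = _init_positions(rng, p.n_daphnia, p.width, p.height, margin, sep)
        std_v = p.speed_sigma / max(np.sqrt(1.0 - p.velocity_persistence**2), 1e-6)
        for pos in positions:
            a = rng.uniform(a_lo, a_hi)
            b = a / rng.uniform(1.6, 2.5)  # elongated body
            swimmers.append(
                _Swimmer(pos, rng.normal(0.0, std_v, 2), (a, max(b, 1.0)), rng.uniform(0, np.pi))
            )

    # --- static droplets (stuck to the glass; absorbed by the background) ---
    droplets = []
    for _ in range(p.n_noise_static):
        c = rng.uniform([margin, margin], [p.width - 1 - margin, p.height - 1 - margin])
        r = rng.uniform(1.5, 3.0)
        level = p.bg_level + 0.45 * (p.fg_level - p.bg_level)
        droplets.append((c, r, level))

    # --- drifting sediment: small irregular clumps moving slowly with the flow ---
    clumps = []
    for _ in range(p.n_noise_drift):
        c = rng.uniform([margin, margin], [p.width - 1 - margin, p.height - 1 - margin])
        drift = rng.uniform(0.05, 0.2) * _unit(rng.normal(size=2))
        grains = rng.normal(0.0, 1.5, size=(rng.integers(3, 6), 2))
        radii = rng.uniform(0.8, 1.6, size=len(grains))
        level = p.bg_level + 0.6 * (p.fg_level - p.bg_level)
        clumps.append([c.astype(np.float64), drift, grains, radii, level])

    frames = np.empty((p.n_frames, p.height, p.width), dtype=np.uint8)
    gt = GroundTruth()
    avoid_radius = 3.0 * a_hi

    for f in range(p.n_frames):
        img = np.full((p.height, p.width), p.bg_level, dtype=np.float64)

        for (cx, cy), r, level in ((c, r, lvl) for c, r, lvl in droplets):
            _stamp_ellipse(img, cy, cx, r, r, 0.0, level, soften=0.5)

        for clump in clumps:
            c, drift, grains, radii, level = clump
            for (gx, gy), r in zip(grains, radii):
                _stamp_ellipse(img, c[1] + gy, c[0] + gx, r, r, 0.0, level, soften=0.5)

        for i, s in enumerate(swimmers):
            mask, y0, x0 = _stamp_ellipse(
                img, s.pos[1], s.pos[0], s.axes[0], s.axes[1], s.theta, p.fg_level
            )
            bbox = _tight_bbox(mask, y0, x0)
            if bbox is not None:
                gt.records.append(GTRecord(f, i + 1, bbox, _mass_center(mask, y0, x0)))

        if p.pixel_noise_sigma > 0:
            img = img + rng.normal(0.0, p.pixel_noise_sigma, img.shape)
        frames[f] = np.clip(img, 0, 255).round().astype(np.uint8)

        # advance motion for the next frame
        for i, s in enumerate(swimmers):
            kick = np.zeros(2)
            for j, o in enumerate(swimmers):
                if j == i:
                    continue
                d = s.pos - o.pos
                dist = np.hypot(*d)
                if 0 < dist < avoid_radius:
                    kick += (d / dist) * 0.8 * (1.0 - dist / avoid_radius)
            s.vel = p.velocity_persistence * s.vel + rng.normal(0.0, p.speed_sigma, 2) + kick
            s.pos = s.pos + s.vel
            s.pos, s.vel = _reflect(s.pos, s.vel, margin, p.width, p.height)
            if np.hypot(*s.vel) > 0.3:
                s.theta = float(np.arctan2(s.vel[1], s.vel[0]))  # body aligns with swim direction

        for clump in clumps:
            clump[0] = clump[0] + clump[1]
            clump[0], clump[1] = _reflect(clump[0], clump[1], margin, p.width, p.height)

    return frames, gt


def _unit(v):
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def _reflect(pos, vel, margin, width, height):
    pos, vel = pos.copy(), vel.copy()
    for k, hi in enumerate((width - 1 - margin, height - 1 - margin)):
        lo = margin
        if pos[k] < lo:
            pos[k] = 2 * lo - pos[k]
            vel[k] = -vel[k]
        elif pos[k] > hi:
            pos[k] = 2 * hi - pos[k]
            vel[k] = -vel[k]
        pos[k] = np.clip(pos[k], lo, hi)
    return pos, vel


# ---------------------------------------------------------------------------
# patch database


def generate_patch_db(
    params: SceneParams, n_per_class: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 8x8 patch set standing in for a manually annotated database.

    Daphnia patches are crops of rendered elongated bodies; noise patches
    cycle through the three nuisance archetypes (droplet, sediment clump,
    faint low-contrast smear). Returns (patches (2n, 8, 8) in [0, 1],
    labels of 'daphnia'/'noise').
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    p = params
    rng = np.random.default_rng(p.seed if seed is None else seed)
    a_lo, a_hi = p.blob_axis_range
    patches, labels = [], []

    def paint(canvas, cy, cx, a, b, theta, level, soften=0.35):
        """Stamp and return a full-canvas mask (canvases here are tiny)."""
        m, y0, x0 = _stamp_ellipse(canvas, cy, cx, a, b, theta, level, soften)
        full = np.zeros(canvas.shape, dtype=bool)
        full[y0 : y0 + m.shape[0], x0 : x0 + m.shape[1]] = m
        return full

    def crop_to_patch(canvas, mask):
        bbox = _tight_bbox(mask)
        x, y, w, h = bbox
        crop = canvas[y : y + h, x : x + w] / 255.0
        if crop.shape == (PATCH_SIZE, PATCH_SIZE):
            return crop
        return area_average_resize(crop, (PATCH_SIZE, PATCH_SIZE))

    side = int(4 * a_hi) + 8
    c0 = side / 2.0

    for _ in range(n_per_class):
        canvas = np.full((side, side), p.bg_level)
        a = rng.uniform(a_lo, a_hi)
        b = a / rng.uniform(1.6, 2.5)
        jit = rng.uniform(-1.0, 1.0, 2)
        mask = paint(canvas, c0 + jit[1], c0 + jit[0], a, max(b, 1.0), rng.uniform(0, np.pi), p.fg_level)
        canvas += rng.normal(0.0, p.pixel_noise_sigma, canvas.shape)
        patches.append(np.clip(crop_to_patch(canvas, mask), 0, 1))
        labels.append("daphnia")

    archetypes = ("droplet", "sediment", "smear")
    for k in range(n_per_class):
        kind = archetypes[k % len(archetypes)]
        canvas = np.full((side, side), p.bg_level)
        if kind == "droplet":
            r = rng.uniform(1.5, 3.0)
            level = p.bg_level + 0.45 * (p.fg_level - p.bg_level)
            mask = paint(canvas, c0, c0, r, r, 0.0, level, soften=0.5)
        elif kind == "sediment":
            grains = rng.normal(0.0, 1.5, size=(int(rng.integers(3, 6)), 2))
            radii = rng.uniform(0.8, 1.6, size=len(grains))
            level = p.bg_level + 0.6 * (p.fg_level - p.bg_level)
            mask = np.zeros(canvas.shape, dtype=bool)
            for (gx, gy), r in zip(grains, radii):
                mask |= paint(canvas, c0 + gy, c0 + gx, r, r, 0.0, level, soften=0.5)
        else:  # faint smear: the ghost left in the difference image by drift
            r = rng.uniform(2.0, 5.0)
            level = p.bg_level + 0.12 * (p.fg_level - p.bg_level)
            mask = paint(canvas, c0, c0, r, r * rng.uniform(0.5, 1.0), rng.uniform(0, np.pi), level, soften=0.8)
        canvas += rng.normal(0.0, p.pixel_noise_sigma, canvas.shape)
        patches.append(np.clip(crop_to_patch(canvas, mask), 0, 1))
        labels.append("noise")

    return np.array(patches), np.array(labels)
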