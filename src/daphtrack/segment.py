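"""Automatic binarization and candidate-object extraction.

The difference image is binarized with a threshold chosen by 2-means
clustering of its pixel values: Lloyd iterations with k=2 on the scalar
intensities, threshold = midpoint of the two cluster means. Foreground
regions are then extracted as 8-connected components, each reported with
its tight bounding box, mass-centre centroid and pixel area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of scalar 2-means thresholding.

    ``threshold`` is exactly ``(mu1 + mu2) / 2``; ``degenerate`` flags the
    all-pixels-identical case, in which the binary mask will be empty
    because binarization is strict (``value > threshold``).
    """

    mu1: float
    mu2: float
    threshold: float
    n_iter: int
    degenerate: bool = False


@dataclass(frozen=True)
class CandidateObject:
    """One connected foreground region in one frame.

    bbox is (x, y, w, h), 0-based, half-open: [x, x+w) x [y, y+h).
    centroid is the component mass centre (u=column, v=row), real-valued.
    """

    frame_index: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    area: int


def kmeans_threshold(
    values: np.ndarray,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: str = "minmax",
) -> ThresholdResult:
    """2-means clustering of scalar pixel values; threshold = mean midpoint.

    ``init='minmax'`` (default) places the initial means at the minimum and
    maximum values, which is deterministic and, for 1-D Lloyd iterations,
    converges to the optimal two-cluster split on every input we test
    against an exhaustive oracle. ``init='random'`` draws two distinct
    initial centers from the data using ``seed``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("kmeans_threshold requires at least one pixel")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return ThresholdResult(lo, hi, lo, 0, degenerate=True)

    if init == "minmax":
        mu = np.array([lo, hi])
    elif init == "random":
        rng = np.random.default_rng(seed)
        uniq = np.unique(v)
        mu = np.sort(rng.choice(uniq, size=2, replace=False).astype(np.float64))
    else:
        raise ValueError(f"unknown init {init!r}")

    assign: np.ndarray | None = None
    n_iter = 0
    while n_iter < max_iter:
        n_iter += 1
        # nearest-mean assignment for two scalar centers is a midpoint cut
        cut = (mu[0] + mu[1]) / 2.0
        new_assign = v > cut
        new_mu = mu.copy()
        if (~new_assign).any():
            new_mu[0] = v[~new_assign].mean()
        if new_assign.any():
            new_mu[1] = v[new_assign].mean()
        stop = (assign is not None and np.array_equal(new_assign, assign)) or bool(
            np.max(np.abs(new_mu - mu)) < tol
        )
        mu, assign = new_mu, new_assign
        if stop:
            break
    mu1, mu2 = float(min(mu)), float(max(mu))
    return ThresholdResult(mu1, mu2, (mu1 + mu2) / 2.0, n_iter)


def binarize(diff_image: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask, true where the difference image exceeds the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(diff_image) > threshold


# 8-connectivity structuring element
_STRUCT8 = np.ones((3, 3), dtype=bool)


def connected_components(
    mask: np.ndarray, min_area: int = 4, frame_index: int = 0
) -> list[CandidateObject]:
    """8-connected components of a binary mask with area >= ``min_area``.

    Components are returned sorted by bounding-box (y, x): deterministic
    regardless of labelling order.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    slices = ndimage.find_objects(labels)
    rows, cols = np.nonzero(mask)
    lab_flat = labels[rows, cols]
    # mass-centre centroids per label
    sum_r = np.bincount(lab_flat, weights=rows, minlength=n + 1)[1:]
    sum_c = np.bincount(lab_flat, weights=cols, minlength=n + 1)[1:]
    objs: list[CandidateObject] = []
    for i in range(n):
        if areas[i] < min_area:
            continue
        sl_y, sl_x = slices[i]
        x, y = sl_x.start, sl_y.start
        w, h = sl_x.stop - sl_x.start, sl_y.stop - sl_y.start
        u = sum_c[i] / areas[i]
        v = sum_r[i] / areas[i]
        objs.append(CandidateObject(frame_index, (x, y, w, h), (float(u), float(v)), int(areas[i])))
    objs.sort(key=lambda o: (o.bbox[1], o.bbox[0]))
    return objs
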