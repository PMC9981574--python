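"""Independent brute-force oracles used to cross-check the implementation.

Each function here deliberately avoids the code path it validates:
exhaustive scans, flood fill, and permutation enumeration only.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def optimal_two_means(values) -> tuple[float, float, float]:
    """Exhaustive optimal 1-D 2-means: scan every cut point of the sorted
    values minimizing within-cluster SSE. Returns (mu1, mu2, midpoint)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    best = None
    for cut in range(1, v.size):
        lo, hi = v[:cut], v[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, lo.mean(), hi.mean())
    _, mu1, mu2 = best
    return float(mu1), float(mu2), float((mu1 + mu2) / 2.0)


def flood_fill_components(mask) -> list[set]:
    """8-connected components by breadth-first flood fill; returns a list of
    pixel-coordinate sets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    H, W = mask.shape
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                comps.append(comp)
    return comps


def best_assignment_total(similarity) -> float:
    """Maximum total similarity over all one-to-one assignments, by
    enumerating every injection of the smaller axis into the larger."""
    S = np.atleast_2d(np.asarray(similarity, dtype=float))
    n_rows, n_cols = S.shape
    if n_rows == 0 or n_cols == 0:
        return 0.0
    transposed = n_rows > n_cols
    if transposed:
        S = S.T
        n_rows, n_cols = n_cols, n_rows
    best = -np.inf
    for perm in itertools.permutations(range(n_cols), n_rows):
        best = max(best, sum(S[i, j] for i, j in enumerate(perm)))
    return float(best)


def exhaustive_id_counts(gt_trajs, hyp_trajs, matches_fn) -> int:
    """Maximum total per-frame identity matches over all one-to-one pairings
    of whole trajectories (including leaving trajectories unpaired).

    ``matches_fn(g, h)`` counts frames where the pair agrees. Returns IDTP.
    """
    gids = list(gt_trajs)
    hids = list(hyp_trajs)
    best = 0
    n = min(len(gids), len(hids))
    for k in range(n + 1):
        for gsub in itertools.combinations(range(len(gids)), k):
            for hperm in itertools.permutations(range(len(hids)), k):
                total = sum(matches_fn(gids[i], hids[j]) for i, j in zip(gsub, hperm))
                best = max(best, total)
    return best


def manual_sobel(patch) -> np.ndarray:
    """Direct 3x3 Sobel convolution with edge replication, no scipy."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = kx.T
    p = np.pad(np.asarray(patch, dtype=float), 1, mode="edge")
    H, W = np.asarray(patch).shape
    gx = np.zeros((H, W))
    gy = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            win = p[i : i + 3, j : j + 3]
            # correlation with the flipped kernel == convolution
            gx[i, j] = (win * kx[::-1, ::-1]).sum()
            gy[i, j] = (win * ky[::-1, ::-1]).sum()
    return np.sqrt(gx**2 + gy**2)
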