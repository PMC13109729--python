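"""Euclidean k-medoids: exact PAM (build + swap) and subsampled CLARA.

PAM follows the classic two-phase scheme. BUILD seeds medoids greedily: the
first medoid minimizes the total distance to all points; each subsequent
medoid maximizes the decrease in total nearest-medoid distance. SWAP then
repeatedly evaluates every (medoid, non-medoid) exchange using the cached
nearest / second-nearest medoid distances (the FastPAM1 bookkeeping) and
applies the best strictly-improving one until a fixed point.

CLARA runs PAM on a handful of random subsamples (classic size 40 + 2k),
extends each medoid set to the full data by nearest-medoid assignment, and
keeps the set with the lowest total distance.

All ties break on the lowest index, so results are deterministic for a
fixed seed; the seed only enters through CLARA's subsampling.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["pam", "clara", "assign_to_medoids"]

_EPS = 1e-12


def _build(dist: np.ndarray, k: int) -> list[int]:
    n = dist.shape[0]
    first = int(np.argmin(dist.sum(axis=1)))
    medoids = [first]
    nearest = dist[first].copy()
    for _ in range(1, k):
        # gain[j]: total reduction in nearest-medoid distance if j is added
        gain = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        j = int(np.argmax(gain))
        medoids.append(j)
        np.minimum(nearest, dist[j], out=nearest)
    return medoids


def _nearest_two(dist: np.ndarray, medoids: np.ndarray):
    """Distances to nearest and second-nearest medoid, plus nearest's index
    into the medoid list."""
    sub = dist[medoids]  # (k, n)
    order = np.argsort(sub, axis=0, kind="stable")
    nearest_idx = order[0]
    nearest = sub[order[0], np.arange(sub.shape[1])]
    second = sub[order[1], np.arange(sub.shape[1])]
    return nearest, second, nearest_idx


def pam(x: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Exact PAM on rows of ``x``; returns k medoid row indices (sorted)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} points")
    dist = cdist(x, x)
    medoids = np.array(_build(dist, k), dtype=int)

    for _ in range(max_iter):
        nearest, second, nearest_idx = _nearest_two(dist, medoids)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        cand = np.flatnonzero(~is_medoid)
        if cand.size == 0:
            break
        dj = dist[cand]  # (m, n): candidate-to-point distances
        base = np.minimum(dj - nearest[None, :], 0.0)  # gain ignoring removal
        delta = np.empty((k, cand.size))
        base_sum = base.sum(axis=1)
        for i in range(k):
            owned = nearest_idx == i
            if not owned.any():
                delta[i] = base_sum
                continue
            repl = (
                np.minimum(dj[:, owned], second[None, owned]) - nearest[None, owned]
            )
            delta[i] = base_sum - base[:, owned].sum(axis=1) + repl.sum(axis=1)
        best = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[best] >= -_EPS:
            break
        medoids = medoids.copy()
        medoids[best[0]] = cand[best[1]]
    return np.sort(medoids)


def assign_to_medoids(x: np.ndarray, medoid_rows: np.ndarray) -> np.ndarray:
    """0-based index of the nearest medoid for every row of ``x``."""
    d = cdist(np.asarray(x, dtype=float), np.asarray(medoid_rows, dtype=float))
    return np.argmin(d, axis=1)


def clara(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_samples: int = 5,
    sample_size: int | None = None,
) -> np.ndarray:
    """CLARA: best-of-``n_samples`` PAM runs on random subsamples."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if sample_size is None:
        sample_size = min(40 + 2 * k, n)
    sample_size = max(sample_size, k)
    best_cost = np.inf
    best_medoids: np.ndarray | None = None
    for _ in range(n_samples):
        idx = np.sort(rng.choice(n, size=sample_size, replace=False))
        local = pam(x[idx], k)
        medoids = idx[local]
        d = cdist(x, x[medoids])
        cost = d.min(axis=1).sum()
        if cost < best_cost - _EPS:
            best_cost = cost
            best_medoids = medoids
    assert best_medoids is not None
    return np.sort(best_medoids)
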