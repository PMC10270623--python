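"""Cluster-tendency and cluster-congruity evaluation.

Hopkins index (exponent-d formulation, axis-aligned bounding-box sampling),
seeded Lloyd k-means with data-point initialization, optimal-assignment
co-assignment congruity between labelings, and bootstrap pair-stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ParameterizationError, ValidationError


@dataclass
class HopkinsResult:
    statistic: float  # mean over repeats, in [0, 1]
    per_repeat: np.ndarray
    m_h: int
    repeats: int
    seed: int


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    seed: int
    inertia: float
    n_iter: int


def hopkins_index(coords, m_h: int = 100, repeats: int = 10, seed: int = 0) -> HopkinsResult:
    """Hopkins cluster-tendency statistic.

    Per repeat: sample ``m_h`` data points (without replacement) and ``m_h``
    uniform points in the data bounding box; with u_i the nearest-data distance
    of each uniform point and w_i the nearest-other-data distance of each
    sampled data point, H = sum(u^d) / (sum(u^d) + sum(w^d)), d the dimension.
    ~0.5 for spatially random data, ->1 for clustered, ->0 for regular grids.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValidationError("coordinates contain non-finite values")
    m, d = X.shape
    if not 1 <= m_h < m:
        raise ParameterizationError(f"m_h must be in [1, {m - 1}]")
    rng = np.random.default_rng(seed)
    tree = cKDTree(X)
    lo, hi = X.min(axis=0), X.max(axis=0)
    hs = np.empty(repeats)
    for r in range(repeats):
        sample_idx = rng.choice(m, size=m_h, replace=False)
        w = tree.query(X[sample_idx], k=2)[0][:, 1]
        uniform = rng.uniform(lo, hi, size=(m_h, d))
        u = tree.query(uniform, k=1)[0]
        u_d, w_d = np.sum(u**d), np.sum(w**d)
        hs[r] = u_d / (u_d + w_d)
    return HopkinsResult(float(hs.mean()), hs, m_h, repeats, seed)


def kmeans_partition(coords, k: int, seed: int = 0, max_iter: int = 300,
                     tol: float = 1e-6, n_init: int = 10) -> ClusteringResult:
    """Lloyd k-means initialized at k distinct seeded data-point indices.

    ``n_init`` restarts are drawn in sequence from the seeded generator and
    the lowest-inertia solution is kept (a single random initialization lands
    in a bad local minimum often enough to make the partition itself
    unreliable).  The initial index sets depend only on (m, k, seed, n_init),
    so the same seed gives identical initializations across different
    representations of the same patients.  Empty clusters are re-seeded at the
    point farthest from its current centroid.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m = X.shape[0]
    if not 2 <= k <= m:
        raise ParameterizationError(f"k must be in [2, {m}]")
    if n_init < 1:
        raise ParameterizationError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best: ClusteringResult | None = None
    for _ in range(n_init):
        centers = X[rng.choice(m, size=k, replace=False)].copy()
        labels = np.zeros(m, dtype=int)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            dist2 = cdist(X, centers, metric="sqeuclidean")
            labels = dist2.argmin(axis=1)
            new_centers = centers.copy()
            for c in range(k):
                mask = labels == c
                if mask.any():
                    new_centers[c] = X[mask].mean(axis=0)
                else:
                    farthest = int(np.argmax(dist2[np.arange(m), labels]))
                    new_centers[c] = X[farthest]
                    labels[farthest] = c
            shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
            centers = new_centers
            if shift < tol:
                break
        inertia = float(np.sum((X - centers[labels]) ** 2))
        if best is None or inertia < best.inertia:
            best = ClusteringResult(k, labels, seed, inertia, n_iter)
    return best


def congruity(labels_a, labels_b) -> float:
    """Percentage of points co-assigned under the overlap-maximizing label matching."""
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValidationError("labelings must cover the same patients")
    k = int(max(a.max(), b.max())) + 1
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (a, b), 1)
    rows, cols = linear_sum_assignment(-table)
    return 100.0 * table[rows, cols].sum() / len(a)


def bootstrap_pair_stability(coords, k: int, fraction: float = 0.1,
                             repeats: int = 20, seed: int = 0) -> float:
    """Mean co-membership agreement of patient pairs across subsample re-clusterings.

    Per repeat, a seeded subsample of ``floor(fraction * m)`` patients is
    re-clustered.  For every pair observed together in >= 2 repeats, the
    fraction of repeat-pairs on which its same/different-cluster status agrees
    is computed; the mean over pairs is returned as a percentage.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m = X.shape[0]
    if not 0.0 < fraction < 1.0:
        raise ParameterizationError("fraction must be in (0, 1)")
    if repeats < 2:
        raise ParameterizationError("repeats must be >= 2")
    n_sub = int(np.floor(fraction * m))
    if n_sub < k:
        raise ParameterizationError(f"subsample size {n_sub} smaller than k={k}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * repeats)
    keys_all, same_all = [], []
    for r in range(repeats):
        rng = np.random.default_rng(child_seeds[2 * r])
        idx = np.sort(rng.choice(m, size=n_sub, replace=False))
        res = kmeans_partition(X[idx], k, seed=int(child_seeds[2 * r + 1]))
        iu, ju = np.triu_indices(n_sub, k=1)
        keys_all.append(idx[iu].astype(np.int64) * m + idx[ju])
        same_all.append(res.labels[iu] == res.labels[ju])
    keys = np.concatenate(keys_all)
    same = np.concatenate(same_all).astype(np.int64)
    uniq, inverse = np.unique(keys, return_inverse=True)
    totals = np.bincount(inverse, minlength=len(uniq))
    sames = np.bincount(inverse, weights=same, minlength=len(uniq)).astype(np.int64)
    mask = totals >= 2
    if not mask.any():
        raise ParameterizationError("no patient pair observed in >= 2 repeats")
    t, s = totals[mask], sames[mask]
    diffs = t - s
    agree = (s * (s - 1) + diffs * (diffs - 1)) / (t * (t - 1))
    return float(agree.mean() * 100.0)
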