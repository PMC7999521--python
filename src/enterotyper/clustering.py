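"""Partitioning Around Medoids (PAM) on a precomputed distance matrix.

Classic Kaufman-Rousseeuw BUILD + SWAP, implemented deterministically:

* BUILD seeds the first medoid with the sample minimizing total distance
  to all others, then greedily adds the medoid giving the largest cost
  reduction.
* SWAP repeatedly evaluates every (medoid, non-medoid) exchange and
  accepts the single best cost-decreasing swap until none remains.

Cost is the *sum* of distances of samples to their nearest medoid.  All
ties break toward the lowest sample index, so runs are bit-reproducible.
Cluster numbers are reassigned so cluster 1 is the largest (ties: the
cluster whose medoid has the lower index), giving stable ET1/ET2/ET3
naming across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio.stats.distance import DistanceMatrix

from .io_tables import EnterotypeLabels


@dataclass
class ClusteringResult:
    k: int
    medoid_indices: np.ndarray  # positions into sample_ids, in cluster order 1..K
    labels: EnterotypeLabels  # 1..K, renumbered by decreasing cluster size
    total_cost: float

    @property
    def medoid_ids(self) -> list[str]:
        return [self.labels.sample_ids[i] for i in self.medoid_indices]


def _as_array(dist) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, DistanceMatrix):
        return dist.data.astype(float, copy=True), list(dist.ids)
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr, [str(i) for i in range(arr.shape[0])]


def _build(d: np.ndarray, k: int, first: int | None = None) -> np.ndarray:
    medoids = [int(np.argmin(d.sum(axis=1))) if first is None else int(first)]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate h: sum of improvements over current nearest
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        np.minimum(nearest, d[h], out=nearest)
    return np.array(sorted(medoids), dtype=int)


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment (0-based cluster = position in medoids)."""
    dm = d[:, medoids]  # n x k
    assign = np.argmin(dm, axis=1)  # argmin -> first minimum -> lowest medoid index
    cost = float(dm[np.arange(d.shape[0]), assign].sum())
    # a medoid always belongs to its own cluster, even if another medoid
    # sits at distance zero
    assign[medoids] = np.arange(len(medoids))
    return assign, cost


def _swap(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    n = d.shape[0]
    medoids = medoids.copy()
    _, cost = _assign(d, medoids)
    while True:
        dm = d[:, medoids]
        order = np.argsort(dm, axis=1)
        nearest_j = order[:, 0]
        nearest_val = dm[np.arange(n), nearest_j]
        if len(medoids) > 1:
            second_val = dm[np.arange(n), order[:, 1]]
        else:
            second_val = np.full(n, np.inf)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        candidates = np.where(~is_medoid)[0]
        if len(candidates) == 0:  # k == n: nothing to swap
            return medoids, cost
        best = (0.0, None, None)
        for j in range(len(medoids)):
            # cost after removing medoid j, before considering the new one
            base = np.where(nearest_j == j, second_val, nearest_val)
            swap_costs = np.minimum(base[None, :], d[candidates]).sum(axis=1)
            jbest = int(np.argmin(swap_costs))
            delta = float(swap_costs[jbest]) - cost
            if delta < best[0] - 1e-12:
                best = (delta, j, int(candidates[jbest]))
        if best[1] is None:
            return medoids, cost
        _, j, h = best
        medoids[j] = h
        medoids = np.array(sorted(medoids), dtype=int)
        _, cost = _assign(d, medoids)


def _renumber(assign: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..K by decreasing size; ties -> lower medoid index."""
    k = len(medoids)
    sizes = np.bincount(assign, minlength=k)
    order = sorted(range(k), key=lambda j: (-sizes[j], medoids[j]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[assign], medoids[order]


#: below this many samples, SWAP descends from every BUILD anchor
MULTI_START_MAX_N = 16


def pam(
    dist,
    k: int,
    multi_start: bool | None = None,
    n_restarts: int = 0,
    seed: int | None = None,
) -> ClusteringResult:
    """Cluster a distance matrix into ``k`` medoid-defined groups.

    Deterministic by default.  At cohort scale this is the classic single
    BUILD + SWAP descent.  On small instances (n <= 16, or whenever
    ``multi_start=True``) the SWAP descent is repeated from a BUILD
    anchored at every sample and the lowest-cost solution kept: plain
    BUILD+SWAP can stall in a local optimum even for n <= 8 (the R
    ``cluster::pam`` default does too), and the multi-start descent
    removes that failure mode while staying deterministic.  ``n_restarts``
    adds seeded random initializations on top.
    """
    d, ids = _as_array(dist)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if multi_start is None:
        multi_start = n <= MULTI_START_MAX_N
    medoids, cost = _swap(d, _build(d, k))
    if multi_start:
        for first in range(n):
            m2, c2 = _swap(d, _build(d, k, first=first))
            if c2 < cost - 1e-12:
                medoids, cost = m2, c2
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            init = np.array(sorted(rng.choice(n, size=k, replace=False)), dtype=int)
            m2, c2 = _swap(d, init)
            if c2 < cost - 1e-12:
                medoids, cost = m2, c2
    assign, cost = _assign(d, medoids)
    labels01, medoids_ordered = _renumber(assign, medoids)
    return ClusteringResult(
        k=k,
        medoid_indices=medoids_ordered,
        labels=EnterotypeLabels(ids, labels01),
        total_cost=cost,
    )


def assign_to_medoids(dist_to_medoids: np.ndarray) -> np.ndarray:
    """Classify new samples to their nearest medoid's cluster (1..K).

    ``dist_to_medoids`` is n_new x K, column order = cluster order.  Ties
    go to the lowest-index medoid.
    """
    d = np.asarray(dist_to_medoids, dtype=float)
    if d.ndim != 2 or d.shape[1] == 0:
        raise ValueError("need a non-empty n_new x K distance block")
    if not np.isfinite(d).all():
        raise ValueError("distances to medoids must be finite")
    return np.argmin(d, axis=1) + 1


def brute_force_pam(dist, k: int) -> tuple[np.ndarray, float]:
    """Exhaustive-search optimum over all C(n, k) medoid sets.

    Testing oracle for small n; returns (medoid indices, optimal cost).
    """
    from itertools import combinations

    d, _ = _as_array(dist)
    n = d.shape[0]
    best_cost, best_medoids = np.inf, None
    for med in combinations(range(n), k):
        cost = d[:, med].min(axis=1).sum()
        if cost < best_cost - 1e-15:
            best_cost, best_medoids = cost, med
    return np.array(best_medoids, dtype=int), float(best_cost)
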