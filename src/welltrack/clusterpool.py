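"""Grouping individuals into behavioral pools for downstream assays.

Two selection schemes are provided:

* :func:`constrained_clusters` — an equal-size k-means variant: k
  centroids are seeded on randomly chosen individuals, then individuals
  and centroid slots are bound greedily by globally closest pair until
  every cluster holds exactly ``size`` members; centroids are recomputed
  as cluster means and the round repeats until the assignment is stable.
  The reference design is 18 clusters of 5 individuals from a population
  of 90; leftover individuals stay unassigned.
* :func:`similar_pools_by_linkage` — agglomerative hierarchical
  clustering (Euclidean metric, average linkage); the disjoint subtrees
  containing exactly ``pool_size`` members are ranked by within-pool mean
  pairwise distance and the tightest ``n_pools`` are returned, yielding
  pools of maximally similar behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, pdist


@dataclass
class PoolAssignment:
    """Result of equal-size clustering.

    ``labels[i]`` is the cluster of individual ``i`` (−1 = unassigned);
    every cluster holds exactly the requested size.
    """

    labels: np.ndarray
    centroids: np.ndarray
    n_iterations: int

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.labels == cluster)[0]

    def cluster_sizes(self) -> np.ndarray:
        k = len(self.centroids)
        return np.array([(self.labels == c).sum() for c in range(k)])


def _greedy_equal_assignment(points: np.ndarray, centroids: np.ndarray,
                             size: int) -> np.ndarray:
    """Bind (individual, centroid) pairs globally closest first.

    Each individual is assigned at most once and each centroid accepts at
    most ``size`` members ("nearest not-occupied centroid"), so the result
    does not depend on any per-individual processing order. Distance ties
    break toward the lowest individual index, then lowest cluster id.
    """
    n, k = len(points), len(centroids)
    dist = cdist(points, centroids)
    order = np.argsort(dist, axis=None, kind="stable")
    labels = np.full(n, -1, dtype=int)
    remaining = np.full(k, size, dtype=int)
    slots = k * size
    for flat in order:
        if slots == 0:
            break
        i, c = divmod(int(flat), k)
        if labels[i] != -1 or remaining[c] == 0:
            continue
        labels[i] = c
        remaining[c] -= 1
        slots -= 1
    return labels


def within_cluster_distance(points: np.ndarray, labels: np.ndarray,
                            centroids: np.ndarray) -> float:
    """Sum of member-to-centroid distances over assigned individuals."""
    total = 0.0
    for c in range(len(centroids)):
        m = labels == c
        if m.any():
            d = points[m] - centroids[c]
            total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def constrained_clusters(sample, k: int, size: int,
                         seed: int | None = None,
                         max_iter: int = 100) -> PoolAssignment:
    """Partition ``k * size`` individuals into ``k`` clusters of exactly
    ``size``, by iterated greedy equal-size assignment.

    Initial centroids are ``k`` distinct individuals drawn with the seed;
    iteration stops when the assignment repeats exactly (the stability
    criterion) or after ``max_iter`` rounds.
    """
    points = np.asarray(sample, dtype=float)
    if points.ndim != 2:
        raise ValueError("sample must be (N, d)")
    n = len(points)
    if k < 1 or size < 1:
        raise ValueError("k and size must be >= 1")
    if k * size > n:
        raise ValueError(f"k*size = {k * size} exceeds population size {n}")
    rng = np.random.default_rng(seed)
    centroids = points[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_labels = _greedy_equal_assignment(points, centroids, size)
        for c in range(k):
            m = new_labels == c
            centroids[c] = points[m].mean(axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return PoolAssignment(labels=labels, centroids=centroids,
                          n_iterations=n_iter)


# ---------------------------------------------------------------------------
# Hierarchical pool selection

def _subtrees_of_size(Z: np.ndarray, n: int, size: int):
    """(leaf-set, min-leaf) of every merge-tree node with exactly ``size``
    leaves (including singletons when size == 1)."""
    leaves: list[set[int]] = [{i} for i in range(n)]
    out = []
    if size == 1:
        out = [(s, min(s)) for s in leaves]
    for a, b, *_ in Z:
        merged = leaves[int(a)] | leaves[int(b)]
        leaves.append(merged)
        if len(merged) == size:
            out.append((merged, min(merged)))
    return out


def similar_pools_by_linkage(sample, pool_size: int,
                             n_pools: int) -> list[np.ndarray]:
    """Behaviorally homogeneous pools from average-linkage clustering.

    Builds the agglomerative merge tree (Euclidean distance, average
    linkage), collects every subtree with exactly ``pool_size`` leaves,
    scores each by the mean pairwise distance among its members, and
    returns the ``n_pools`` tightest pairwise-disjoint ones (ties break
    toward the lowest member index). Raises if the tree does not contain
    enough disjoint subtrees of the requested size.
    """
    points = np.asarray(sample, dtype=float)
    if points.ndim != 2:
        raise ValueError("sample must be (N, d)")
    n = len(points)
    if pool_size < 1 or n_pools < 1:
        raise ValueError("pool_size and n_pools must be >= 1")
    if n < n_pools * pool_size:
        raise ValueError("not enough individuals for the requested pools")
    Z = linkage(points, method="average", metric="euclidean")
    candidates = _subtrees_of_size(Z, n, pool_size)
    scored = []
    for members, min_leaf in candidates:
        idx = sorted(members)
        tight = float(pdist(points[idx]).mean()) if pool_size > 1 else 0.0
        scored.append((tight, min_leaf, idx))
    scored.sort(key=lambda t: (t[0], t[1]))
    pools: list[np.ndarray] = []
    used: set[int] = set()
    for _, _, idx in scored:
        if used.isdisjoint(idx):
            pools.append(np.asarray(idx))
            used.update(idx)
            if len(pools) == n_pools:
                return pools
    # Degenerate trees (e.g. tied distances merging as a chain) may hold
    # fewer than n_pools exact-size subtrees; fill the remainder from the
    # larger subtrees in merge order, chunking unused members by index.
    members: list[set[int]] = [{i} for i in range(n)]
    for a, b, *_ in Z:
        merged = members[int(a)] | members[int(b)]
        members.append(merged)
        if len(merged) <= pool_size:
            continue
        free = sorted(set(merged) - used)
        while len(free) >= pool_size and len(pools) < n_pools:
            pools.append(np.asarray(free[:pool_size]))
            used.update(free[:pool_size])
            free = free[pool_size:]
        if len(pools) == n_pools:
            return pools
    raise ValueError(
        f"only {len(pools)} disjoint pools of size {pool_size} found "
        f"({n_pools} requested)")


def assignment_table(assignment: PoolAssignment, sample,
                     center: np.ndarray | None = None):
    """Assignment as a DataFrame with the polar coordinates of each
    cluster centroid (for pooling designs keyed on distance/angle to the
    population's mean behavior)."""
    import pandas as pd

    from .varstats import polar_coordinates

    points = np.asarray(sample, dtype=float)
    r, theta = polar_coordinates(
        assignment.centroids,
        center=points.mean(axis=0) if center is None else center)
    rows = []
    for i, lab in enumerate(assignment.labels):
        rows.append({
            "individual": i,
            "cluster": int(lab),
            "centroid_r": float(r[lab]) if lab >= 0 else np.nan,
            "centroid_theta": float(theta[lab]) if lab >= 0 else np.nan,
        })
    return pd.DataFrame(rows)
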