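"""Independent brute-force reference implementations used only by the tests."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform


def dbscan_reference(points: np.ndarray, eps: float, minpts: int):
    """O(n^2) density-reachability closure.

    Returns (core mask, noise mask, core partition as a set of frozensets).
    Border points are ambiguous under DBSCAN (they join whichever adjacent
    core cluster claims them first), so the reference exposes the
    unambiguous parts: the core-point partition and the noise set.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return np.zeros(0, bool), np.zeros(0, bool), set()
    dist = squareform(pdist(points)) if n > 1 else np.zeros((n, n))
    within = dist <= eps
    core = within.sum(axis=1) >= minpts  # diagonal counts the point itself

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    core_idx = np.flatnonzero(core)
    for a in core_idx:
        for b in core_idx:
            if a < b and within[a, b]:
                union(a, b)
    components = {}
    for i in core_idx:
        components.setdefault(find(i), set()).add(i)
    partition = {frozenset(c) for c in components.values()}
    # noise: non-core points with no core neighbor within eps
    has_core_neighbor = (within & core[None, :]).any(axis=1)
    noise = ~core & ~has_core_neighbor
    return core, noise, partition


def check_dbscan_labels(points, eps, minpts, labels) -> None:
    """Assert that DBSCAN labels agree with the brute-force closure."""
    labels = np.asarray(labels)
    core, noise, partition = dbscan_reference(points, eps, minpts)
    assert np.array_equal(labels == -1, noise), "noise sets differ"
    # the core points of each labelled cluster must form exactly one reference component
    got = set()
    for lab in np.unique(labels[labels != -1]):
        members = np.flatnonzero(labels == lab)
        core_members = frozenset(i for i in members if core[i])
        assert core_members, f"cluster {lab} has no core point"
        got.add(core_members)
    assert got == partition, "core partitions differ"
    # border points must be adjacent to a core point of their own cluster
    dist = squareform(pdist(points)) if len(points) > 1 else np.zeros((1, 1))
    for i in np.flatnonzero((labels != -1) & ~core):
        same = np.flatnonzero((labels == labels[i]) & core)
        assert (dist[i, same] <= eps).any(), f"border point {i} detached from its cluster"


def welch_free_t(a, b):
    """Closed-form pooled-variance two-sample t statistic and p-value."""
    import math

    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p
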