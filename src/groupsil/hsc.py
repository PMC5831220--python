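"""Hierarchical sample clustering (UPGMA) on a precomputed distance matrix.

Average linkage on ``1 - Spearman r`` distances is the conventional way to
draw a sample dendrogram next to a group-silhouette score. The
implementation is the naive O(n^3) agglomeration — sample counts are
small — with a fixed tie-break so results are identical across platforms:
among candidate pairs at the minimal distance, the pair with the
lexicographically smallest (node_a, node_b) ids is merged, where leaves
are numbered 0..n-1 in input order and internal nodes n, n+1, ... in
creation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DistanceMatrix


@dataclass
class Dendrogram:
    """Agglomeration record: (node_a, node_b, height, new_node_id) merges."""

    merges: list[tuple[int, int, float, int]]
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]


def average_linkage(D: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of the samples in ``D``.

    Cluster-to-cluster distance is the unweighted mean over all cross
    pairs of the original distances, recomputed from scratch at each step.
    Merge heights are non-decreasing (average linkage is monotone).
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.all(np.isfinite(D.d)):
        raise ValueError("non-finite distances")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(members) > 1:
        best = None
        active = sorted(members)
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                dist = float(D.d[np.ix_(members[a], members[b])].mean())
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        members[next_id] = members.pop(a) + members.pop(b)
        merges.append((a, b, dist, next_id))
        next_id += 1
    return Dendrogram(merges, list(D.sample_ids))


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Leaf-pair merge heights as a distance matrix (always ultrametric)."""
    n = tree.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = np.zeros((n, n))
    for a, b, h, new_id in tree.merges:
        for i in members[a]:
            for j in members[b]:
                d[i, j] = d[j, i] = h
        members[new_id] = members.pop(a) + members.pop(b)
    return DistanceMatrix(list(tree.leaves), d)
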