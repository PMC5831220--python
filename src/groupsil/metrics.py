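"""Spearman-based sample distances and group-silhouette scores.

The distance between two samples is ``1 - rho`` where ``rho`` is
Spearman's rank correlation between their expression columns (midranks
for ties), so distances live in [0, 2] and a monotone transform of one
sample's values leaves all its distances unchanged.

The silhouette statistic is Rousseeuw's, with the clusters replaced by
*predefined* groups: for sample i with own-group mean distance u_i and
nearest-other-group mean distance v_i,

    s_i = (v_i - u_i) / max(u_i, v_i),

and the average silhouette AS is the mean s_i over all samples. AS near 1
means the grouping separates cleanly in expression space; AS near 0 means
the groups are intermingled (the situation in which few differentially
expressed genes are expected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .iolib import ExpressionMatrix, GroupLabels


class ConstantSampleError(ValueError):
    """A sample column is constant, so its rank correlation is undefined."""


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample ``1 - Spearman r`` distances."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance grid shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12) or np.any(self.d > 2 + 1e-12):
            raise ValueError("distances outside [0, 2]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass
class SilhouetteResult:
    """Per-sample silhouettes and their average (AS)."""

    per_sample: dict[str, float]
    AS: float
    per_group_mean: dict[str, float]
    u: dict[str, float]
    v: dict[str, float]


def spearman_distance(m: ExpressionMatrix) -> DistanceMatrix:
    """Pairwise ``1 - Spearman rho`` between sample columns.

    Expects an already filtered matrix (every gene non-zero somewhere,
    duplicate rows collapsed). Ties receive average ranks, which count
    data guarantee in the low-expression range.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    constant = np.all(m.values == m.values[0, :], axis=0) if m.n_genes else np.ones(m.n_samples, bool)
    if m.n_genes < 2 or np.any(constant):
        bad = [s for s, c in zip(m.sample_ids, constant) if c]
        raise ConstantSampleError(
            f"rank correlation undefined for constant sample column(s): {bad}"
        )
    ranks = rankdata(m.values, axis=0)
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(list(m.sample_ids), d)


def silhouette_scores(D: DistanceMatrix, g: GroupLabels) -> SilhouetteResult:
    """Silhouette of each sample against its *predefined* group.

    With two groups v_i is simply the mean distance to the other group;
    with more, v_i is the mean distance to the nearest other group. A
    sample alone in its group scores 0 (the indifferent value), as does a
    sample whose relevant distances are all zero.
    """
    labels = g.restrict(D.sample_ids)
    groups = labels.groups
    if len(groups) < 2:
        raise ValueError("silhouette requires at least 2 groups with members")
    idx_of_group = {
        grp: np.array([D.sample_ids.index(s) for s in labels.members(grp)])
        for grp in groups
    }
    per_sample: dict[str, float] = {}
    u_map: dict[str, float] = {}
    v_map: dict[str, float] = {}
    for i, s in enumerate(D.sample_ids):
        own = labels.assignment[s]
        own_idx = idx_of_group[own]
        others = own_idx[own_idx != i]
        v = min(float(D.d[i, idx_of_group[grp]].mean()) for grp in groups if grp != own)
        v_map[s] = v
        if others.size == 0:
            u_map[s] = float("nan")
            per_sample[s] = 0.0
            continue
        u = float(D.d[i, others].mean())
        u_map[s] = u
        denom = max(u, v)
        per_sample[s] = 0.0 if denom == 0.0 else (v - u) / denom
    as_value = float(np.mean(list(per_sample.values())))
    per_group_mean = {
        grp: float(np.mean([per_sample[s] for s in labels.members(grp)]))
        for grp in groups
    }
    return SilhouetteResult(per_sample, as_value, per_group_mean, u_map, v_map)


def group_distance_summary(D: DistanceMatrix, g: GroupLabels) -> dict:
    """Mean intra-group and pairwise inter-group distances.

    Returns ``{"intra": {group: mean | None}, "inter": {(g1, g2): mean}}``
    with ``None`` for singleton groups (no intra pair exists).
    """
    labels = g.restrict(D.sample_ids)
    groups = labels.groups
    idx = {
        grp: np.array([D.sample_ids.index(s) for s in labels.members(grp)])
        for grp in groups
    }
    intra: dict[str, float | None] = {}
    for grp in groups:
        ii = idx[grp]
        if ii.size < 2:
            intra[grp] = None
        else:
            sub = D.d[np.ix_(ii, ii)]
            intra[grp] = float(sub[np.triu_indices(ii.size, k=1)].mean())
    inter: dict[tuple[str, str], float] = {}
    for a_pos, ga in enumerate(groups):
        for gb in groups[a_pos + 1 :]:
            inter[(ga, gb)] = float(D.d[np.ix_(idx[ga], idx[gb])].mean())
    return {"intra": intra, "inter": inter}
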