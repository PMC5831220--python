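"""Gene filters applied before distance/DE computation.

Two filters are used throughout: the *zero filter* drops genes whose value
is zero in every sample, and the *unique filter* collapses genes whose
expression vector across samples is identical, keeping the first
occurrence. DE analysis conventionally runs on the zero-filtered matrix;
distance, silhouette and clustering run on the zero-then-unique-filtered
matrix, which damps the influence of the low-count floor on rank
correlations. A log2 floor transform is provided for raw microarray
signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iolib import ExpressionMatrix, FormatError, ModeError, MODE_CONTINUOUS


class EmptyMatrixError(FormatError):
    """A filter removed every gene."""


@dataclass
class FilterReport:
    """Gene counts surviving each applied filter stage.

    Stages that were not applied carry the count of the previous stage, so
    the monotone invariant n_input >= n_after_zero_filter >=
    n_after_unique_filter always holds. ``collapsed_group_sizes`` lists the
    duplicate-class sizes seen by the unique filter (all 1 when every row
    is distinct).
    """

    n_input: int
    n_after_zero_filter: int
    n_after_unique_filter: int
    collapsed_group_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_zero_filter >= self.n_after_unique_filter >= 0):
            raise ValueError("filter counts must be monotone non-increasing")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_zero_filter": self.n_after_zero_filter,
            "n_after_unique_filter": self.n_after_unique_filter,
            "collapsed_group_sizes": list(self.collapsed_group_sizes),
        }


def zero_filter(m: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with at least one non-zero value; preserve gene order."""
    keep = np.flatnonzero(np.any(m.values != 0, axis=1))
    if keep.size == 0:
        raise EmptyMatrixError("zero filter removed every gene")
    out = m.select_genes(keep)
    report = FilterReport(m.n_genes, out.n_genes, out.n_genes)
    return out, report


def unique_filter(m: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Collapse genes with identical expression vectors across all samples.

    Row identity is exact equality of stored values; the representative of
    each duplicate class is its first occurrence and output order is the
    order of first occurrences.
    """
    _, first_idx, counts = np.unique(
        m.values, axis=0, return_index=True, return_counts=True
    )
    order = np.argsort(first_idx, kind="stable")
    keep = first_idx[order]
    sizes = counts[order]
    out = m.select_genes(keep)
    report = FilterReport(m.n_genes, m.n_genes, out.n_genes, [int(c) for c in sizes])
    return out, report


def filter_genes(
    m: ExpressionMatrix, unique: bool = True
) -> tuple[ExpressionMatrix, FilterReport]:
    """Zero filter followed (optionally) by the unique filter."""
    zeroed, zrep = zero_filter(m)
    if not unique:
        return zeroed, zrep
    collapsed, urep = unique_filter(zeroed)
    report = FilterReport(
        m.n_genes,
        zrep.n_after_zero_filter,
        urep.n_after_unique_filter,
        urep.collapsed_group_sizes,
    )
    return collapsed, report


def log2_floor(m: ExpressionMatrix) -> ExpressionMatrix:
    """Floor continuous signals at 1 and log2-transform them.

    This is the conventional pre-treatment for raw microarray intensities;
    values below 1 become exactly 0 after the transform. Count matrices
    are rejected — the transform is a microarray convention only.
    """
    if m.mode != MODE_CONTINUOUS:
        raise ModeError("log2_floor applies only to continuous matrices")
    values = np.log2(np.maximum(m.values, 1.0))
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), values, MODE_CONTINUOUS)
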