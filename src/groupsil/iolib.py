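"""Text-format IO for expression matrices, group labels and dendrograms.

The on-disk conventions are deliberately plain: an expression matrix is a
TSV/CSV with a header row of sample ids and a first column of gene ids;
group labels are a two-column table mapping each sample to its group; trees
are serialized as Newick. Missing values are never tolerated — every filter
and distance downstream assumes a complete matrix.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODE_COUNTS = "counts"
MODE_CONTINUOUS = "continuous"
_MODES = (MODE_COUNTS, MODE_CONTINUOUS)


class FormatError(ValueError):
    """Malformed input: non-numeric, negative, or missing cells."""


class IdCollisionError(FormatError):
    """Duplicate gene or sample identifiers."""


class ModeError(FormatError):
    """Value/mode mismatch (e.g. fractional cell in a counts matrix)."""


@dataclass
class ExpressionMatrix:
    """A dense genes-by-samples expression grid.

    ``mode`` declares whether cells are RNA-seq integer counts
    (``"counts"``) or continuous signals such as log2 microarray
    intensities (``"continuous"``). Orientation is fixed: genes in rows,
    samples in columns.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in _MODES:
            raise ModeError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IdCollisionError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdCollisionError("duplicate sample ids")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise FormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite or missing cell values")
        if np.any(self.values < 0):
            raise FormatError("negative cell values")
        if self.mode == MODE_COUNTS and not np.all(self.values == np.round(self.values)):
            raise ModeError("mode=counts but matrix contains fractional values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), mode)

    def select_genes(self, row_indices) -> "ExpressionMatrix":
        idx = np.asarray(row_indices)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            self.mode,
        )

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, cols], self.mode
        )


@dataclass
class GroupLabels:
    """Sample-to-group assignment defining the grouping under evaluation."""

    assignment: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_order:
            seen: list[str] = []
            for g in self.assignment.values():
                if g not in seen:
                    seen.append(g)
            self.group_order = seen
        for s, g in self.assignment.items():
            if not str(g):
                raise FormatError(f"sample {s!r} has an empty group id")
        extra = set(self.assignment.values()) - set(self.group_order)
        if extra:
            raise FormatError(f"groups missing from group_order: {sorted(extra)}")

    @property
    def groups(self) -> list[str]:
        present = set(self.assignment.values())
        return [g for g in self.group_order if g in present]

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def restrict(self, sample_ids) -> "GroupLabels":
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise KeyError(f"samples without a group label: {missing}")
        sub = {s: self.assignment[s] for s in sample_ids}
        order = [g for g in self.group_order if g in set(sub.values())]
        return GroupLabels(sub, order)


def _infer_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path, mode: str, delimiter: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from a delimited text file.

    The file must have a header row of sample ids and a first column of
    gene ids; the body must be numeric and non-negative. Any NA token is a
    hard error — incomplete matrices are not supported.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, na_filter=False, dtype=str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise IdCollisionError(f"duplicate gene or sample ids in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if mode == MODE_COUNTS and values.size and np.any(values != np.round(values)):
        bad = np.argwhere(values != np.round(values))[0]
        raise ModeError(
            f"mode=counts but {path} has fractional value at gene "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), values, mode)


def write_matrix(m: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    """Write a matrix in the same layout :func:`read_matrix` expects."""
    sep = _infer_delimiter(path, delimiter)
    df = m.to_frame()
    if m.mode == MODE_COUNTS:
        df = df.astype(np.int64)
    _atomic_write_text(path, df.to_csv(sep=sep, index_label="gene_id"))


def read_labels(path, delimiter: str | None = None) -> GroupLabels:
    """Read a two-column (sample_id, group_id) table.

    A header row is tolerated when its first field is literally
    ``sample_id``. Group order is order of first appearance.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, na_filter=False, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"label table {path} must have exactly 2 columns")
    if len(df) and df.iloc[0, 0] == "sample_id":
        df = df.iloc[1:]
    assignment: dict[str, str] = {}
    order: list[str] = []
    for sample, group in df.itertuples(index=False):
        if sample in assignment:
            raise FormatError(f"sample {sample!r} listed more than once in {path}")
        if not group:
            raise FormatError(f"sample {sample!r} has an empty group id")
        assignment[sample] = group
        if group not in order:
            order.append(group)
    if not assignment:
        raise FormatError(f"empty label table {path}")
    return GroupLabels(assignment, order)


def write_labels(labels: GroupLabels, path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    lines = [f"{s}{sep}{g}" for s, g in labels.assignment.items()]
    _atomic_write_text(path, "\n".join(lines) + "\n")


_NEWICK_META = re.compile(r"[\s()\[\]:;,']")


def _newick_name(name: str) -> str:
    if _NEWICK_META.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree, path) -> None:
    """Serialize a dendrogram (see :mod:`groupsil.hsc`) as Newick.

    Node heights are halved so that the leaf-to-leaf path length through
    the tree equals the cophenetic distance (merge height) — the standard
    dendrogram convention.
    """
    _atomic_write_text(path, newick_string(tree) + "\n")


def newick_string(tree) -> str:
    leaves = tree.leaves
    if len(leaves) < 2:
        raise ValueError("cannot serialize a tree with fewer than 2 leaves")
    n = len(leaves)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    root = n - 1
    for a, b, h, new_id in tree.merges:
        height[new_id] = h
        children[new_id] = (a, b)
        root = new_id

    def render(node: int, parent_h: float) -> str:
        blen = (parent_h - height[node]) / 2.0
        if node < n:
            return f"{_newick_name(leaves[node])}:{blen:.10g}"
        a, b = children[node]
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{blen:.10g}"

    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"


def _atomic_write_text(path, text: str) -> None:
    path = os.fspath(path)
    tmp = f"{path}.tmp.{os.getpid()}"
    with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
    os.replace(tmp, path)
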