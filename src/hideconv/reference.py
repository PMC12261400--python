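"""Consensus cell-type reference profiles and gene selection.

A reference matrix X holds one archetypic expression profile per cell type in
its columns. Consensus profiles are arithmetic means of depth-normalized
single-cell profiles (counts per 10k), which makes the reference invariant to
global sequencing-depth changes; profiles for internal tree nodes average
over all descendant cells, which equals the cell-count-weighted mean of the
children's profiles.

Gene filtering keeps the k genes with the highest variance computed across
the reference columns (default 5000), ties broken by input gene order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import CellData
from .tree import CellTree, TreeError

__all__ = [
    "build_reference",
    "leaf_cell_counts",
    "expand_reference",
    "select_top_variance_genes",
    "restrict_genes",
    "DEFAULT_TOP_K",
]

DEFAULT_TOP_K = 5000


def _depth_normalize(counts: pd.DataFrame, target_sum: float) -> np.ndarray:
    values = counts.to_numpy(dtype=float)
    depths = values.sum(axis=0)
    if (depths == 0).any():
        bad = counts.columns[depths == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    return values * (target_sum / depths)[None, :]


def build_reference(
    cells: CellData,
    tree: CellTree,
    level: str | Sequence[str],
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Consensus profiles (genes x level nodes) from annotated cells.

    Each column is the mean of the depth-normalized count vectors of all
    cells whose leaf label descends from (or equals) the level node.
    """
    nodes = tree.level(level)
    unknown = sorted(set(cells.labels) - set(tree.leaves))
    if unknown:
        raise TreeError(f"cell labels are not tree leaves: {unknown!r}")
    norm = _depth_normalize(cells.counts, target_sum)
    labels = np.asarray(cells.labels)
    columns = np.empty((cells.counts.shape[0], len(nodes)))
    for j, node in enumerate(nodes):
        mask = np.isin(labels, tree.leaf_descendants(node))
        if not mask.any():
            raise ValueError(f"no cells annotated under node {node!r}")
        columns[:, j] = norm[:, mask].mean(axis=1)
    return pd.DataFrame(columns, index=cells.counts.index, columns=list(nodes))


def leaf_cell_counts(labels: pd.Series, leaves: Sequence[str] | None = None) -> pd.Series:
    """Number of annotated cells per leaf type (used to weight aggregation)."""
    counts = labels.value_counts()
    if leaves is not None:
        counts = counts.reindex(list(leaves), fill_value=0)
    return counts.astype(float)


def expand_reference(
    leaf_reference: pd.DataFrame,
    tree: CellTree,
    level: str | Sequence[str],
    cell_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Reference at a coarser level from the leaf reference.

    The column of an internal node is the cell-count-weighted mean of its
    descendant leaves' columns — identical to :func:`build_reference` run on
    the same cell pool at that level. Equal weights are used when counts are
    not supplied.
    """
    nodes = tree.level(level)
    missing = sorted(set(tree.leaves) - set(leaf_reference.columns))
    if missing:
        raise TreeError(f"leaf reference lacks columns for leaves: {missing!r}")
    if cell_counts is None:
        cell_counts = pd.Series(1.0, index=list(tree.leaves))
    out = np.empty((leaf_reference.shape[0], len(nodes)))
    for j, node in enumerate(nodes):
        leaves = list(tree.leaf_descendants(node))
        w = cell_counts.reindex(leaves).to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"no cells annotated under node {node!r}")
        out[:, j] = leaf_reference[leaves].to_numpy() @ (w / w.sum())
    return pd.DataFrame(out, index=leaf_reference.index, columns=list(nodes))


def select_top_variance_genes(ref: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.Index:
    """Indices of the k genes with the largest row variance across columns.

    Descending by variance; ties broken by input gene order; ``k >= p``
    returns all genes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    variances = ref.to_numpy().var(axis=1)
    order = np.argsort(-variances, kind="stable")
    return ref.index[order[:k]]


def restrict_genes(obj: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Subset and reorder a genes x anything table to the given gene index."""
    unknown = [g for g in genes if g not in obj.index]
    if unknown:
        raise KeyError(f"unknown gene id(s): {unknown[:10]!r}")
    return obj.loc[list(genes)]
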