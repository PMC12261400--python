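"""Synthetic annotated single-cell data and pseudo-bulk mixtures.

The generator emulates the training design used throughout the package:
an annotated single-cell compendium with a multi-level cell-type hierarchy,
split 50/50 into training and test halves, from which pseudo-bulks of
``cells_per_bulk`` (default 100) randomly drawn cells are summed, with the
drawn cell-type counts providing exact ground-truth proportions. Defaults
follow the full study design (20 000 training mixtures, 10 test batches of
1000); tests and the packaged benchmark run the same machinery at reduced
sizes.

Expression model: each tree node perturbs a random marker subset of its
parent's log-mean profile by ``effect_size`` (natural-log fold change, random
sign), so sibling leaves are strongly correlated while distant types differ
in many genes — the regime in which hierarchical deconvolution is expected
to help. Counts are negative binomial (gamma–Poisson) around the per-leaf
mean scaled to a log-normally varying library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .tree import CellTree, parse_tree

__all__ = [
    "SimConfig",
    "CellData",
    "benchmark_tree",
    "simulate_cells",
    "split_train_test",
    "make_pseudo_bulks",
    "simulate_dataset",
]


def benchmark_tree() -> CellTree:
    """The packaged three-level synthetic benchmark hierarchy (11 leaves).

    Mixes subdivided and pass-through branches so that the stand-in level
    convention, single-child bypass and ξ-normalization are all exercised.
    """
    doc = {
        "tree": [
            {"name": "A", "children": [
                {"name": "A1", "children": [{"name": "A1a"}, {"name": "A1b"}]},
                {"name": "A2", "children": [{"name": "A2a"}, {"name": "A2b"}, {"name": "A2c"}]},
            ]},
            {"name": "B", "children": [
                {"name": "B1", "children": [{"name": "B1a"}, {"name": "B1b"}]},
                {"name": "B2"},
            ]},
            {"name": "C"},
            {"name": "D", "children": [{"name": "D1"}, {"name": "D2"}]},
        ],
        "levels": [
            {"name": "major", "nodes": ["A", "B", "C", "D"]},
            {"name": "minor", "nodes": ["A1", "A2", "B1", "B2", "C", "D1", "D2"]},
            {"name": "leaf", "nodes": ["A1a", "A1b", "A2a", "A2b", "A2c",
                                       "B1a", "B1b", "B2", "C", "D1", "D2"]},
        ],
    }
    return parse_tree(doc)


@dataclass
class SimConfig:
    """Generator settings; defaults are the full study conditions."""

    tree: CellTree = field(default_factory=benchmark_tree)
    genes: int = 2000
    cells_per_leaf: int = 200
    marker_fraction: float = 0.05
    effect_size: float = 1.0
    dispersion: float = 0.4
    depth_mean: float = 1500.0
    depth_sigma: float = 0.25
    seed: int = 0
    n_train_bulks: int = 20000
    cells_per_bulk: int = 100
    test_batches: int = 10
    test_batch_size: int = 1000

    def __post_init__(self) -> None:
        for name in ("genes", "cells_per_leaf", "n_train_bulks", "cells_per_bulk",
                     "test_batches", "test_batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ValueError("marker_fraction must lie in [0, 1]")
        for name in ("effect_size", "dispersion", "depth_mean", "depth_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_manifest(self) -> dict:
        d = asdict(self)
        from .tree import tree_to_document

        d["tree"] = tree_to_document(self.tree)
        return d


@dataclass
class CellData:
    """Annotated single-cell counts: genes x cells plus a leaf label per cell."""

    counts: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.labels.index):
            raise ValueError("labels must be indexed by the count matrix columns")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def _leaf_log_means(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Hierarchical log-mean profiles: each node perturbs its parent's markers."""
    base = rng.normal(0.0, 1.0, cfg.genes)
    n_markers = int(round(cfg.marker_fraction * cfg.genes))
    log_means: dict[str, np.ndarray] = {}

    def walk(node: str, parent_mean: np.ndarray) -> None:
        mean = parent_mean.copy()
        if n_markers > 0:
            markers = rng.choice(cfg.genes, size=n_markers, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_markers)
            mean[markers] += signs * cfg.effect_size
        log_means[node] = mean
        for child in cfg.tree.children_of[node]:
            walk(child, mean)

    for root in cfg.tree.roots:
        walk(root, base)
    return {leaf: log_means[leaf] for leaf in cfg.tree.leaves}


def simulate_cells(cfg: SimConfig) -> CellData:
    """Draw ``cells_per_leaf`` negative-binomial cells for every leaf type.

    Fully reproducible from ``cfg.seed``; the seed also feeds the independent
    streams used by :func:`split_train_test` and :func:`make_pseudo_bulks`
    when run through :func:`simulate_dataset`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    log_means = _leaf_log_means(cfg, rng)
    leaves = cfg.tree.leaves
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for leaf in leaves:
        rel = np.exp(log_means[leaf])
        rel = rel / rel.sum()
        depths = cfg.depth_mean * np.exp(
            rng.normal(-0.5 * cfg.depth_sigma**2, cfg.depth_sigma, cfg.cells_per_leaf)
        )
        mu = rel[:, None] * depths[None, :]
        if cfg.dispersion > 0:
            shape = 1.0 / cfg.dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        blocks.append(rng.poisson(lam).astype(np.int64))
        labels.extend([leaf] * cfg.cells_per_leaf)
    counts = np.concatenate(blocks, axis=1)
    cell_ids = [f"cell_{i:06d}" for i in range(counts.shape[1])]
    gene_ids = [f"gene_{i:05d}" for i in range(cfg.genes)]
    table = pd.DataFrame(counts, index=gene_ids, columns=cell_ids, dtype=float)
    return CellData(table, pd.Series(labels, index=cell_ids, name="cell_type"))


def split_train_test(cells: CellData, seed: int) -> tuple[CellData, CellData]:
    """Stratified 50/50 split per leaf; the odd cell goes to a seeded side."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    train_ids: list[str] = []
    test_ids: list[str] = []
    for leaf in cells.labels.unique():
        ids = np.asarray(cells.labels.index[cells.labels == leaf])
        if len(ids) < 2:
            raise ValueError(f"cell type {leaf!r} has fewer than 2 cells; cannot split")
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        if len(ids) % 2 == 1 and rng.random() < 0.5:
            half += 1
        train_ids.extend(ids[perm[:half]])
        test_ids.extend(ids[perm[half:]])
    train_ids.sort()
    test_ids.sort()

    def subset(ids: list[str]) -> CellData:
        return CellData(cells.counts[ids], cells.labels.loc[ids])

    return subset(train_ids), subset(test_ids)


def make_pseudo_bulks(
    cells: CellData,
    n_bulks: int,
    cells_per_bulk: int,
    seed: int,
    leaves: Sequence[str] | None = None,
    return_indices: bool = False,
):
    """Sum randomly drawn cells into pseudo-bulks with exact truth proportions.

    Cells are drawn uniformly from the whole pool, without replacement within
    a bulk and with replacement across bulks, so mixture compositions follow
    the pool's marginal cell-type frequencies.

    Returns ``(bulks, truth)``: bulks genes x n_bulks, truth leaf x n_bulks
    with columns summing to one (entries are multiples of 1/cells_per_bulk).
    """
    if n_bulks < 1 or cells_per_bulk < 1:
        raise ValueError("n_bulks and cells_per_bulk must be >= 1")
    if cells_per_bulk > cells.n_cells:
        raise ValueError("cells_per_bulk exceeds the available cell pool")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    if leaves is None:
        leaves = list(dict.fromkeys(cells.labels))
    leaf_pos = {l: i for i, l in enumerate(leaves)}
    label_codes = np.asarray([leaf_pos[l] for l in cells.labels])

    draws = np.empty((n_bulks, cells_per_bulk), dtype=np.int64)
    for b in range(n_bulks):
        draws[b] = rng.choice(cells.n_cells, size=cells_per_bulk, replace=False)

    # bulks = counts @ indicator(cell, bulk); sparse keeps this cheap at scale
    indicator = scipy.sparse.csc_matrix(
        (
            np.ones(n_bulks * cells_per_bulk),
            (draws.ravel(), np.repeat(np.arange(n_bulks), cells_per_bulk)),
        ),
        shape=(cells.n_cells, n_bulks),
    )
    bulk_values = (indicator.T @ cells.counts.to_numpy().T).T
    bulk_ids = [f"bulk_{i:05d}" for i in range(n_bulks)]
    bulks = pd.DataFrame(bulk_values, index=cells.counts.index, columns=bulk_ids)

    truth_counts = np.zeros((len(leaves), n_bulks))
    for b in range(n_bulks):
        truth_counts[:, b] = np.bincount(label_codes[draws[b]], minlength=len(leaves))
    truth = pd.DataFrame(
        truth_counts / cells_per_bulk, index=list(leaves), columns=bulk_ids
    )
    if return_indices:
        return bulks, truth, draws
    return bulks, truth


def simulate_dataset(cfg: SimConfig) -> dict:
    """Full study pipeline: cells -> split -> training and test pseudo-bulks.

    Returns a dict with ``cells``, ``train_cells``, ``test_cells``,
    ``bulks_train``, ``truth_train`` and lists ``bulks_test`` /
    ``truth_test`` (one entry per batch). Truth matrices are over the tree's
    leaves in tree order.
    """
    cells = simulate_cells(cfg)
    train_cells, test_cells = split_train_test(cells, cfg.seed)
    leaves = list(cfg.tree.leaves)
    bulks_train, truth_train = make_pseudo_bulks(
        train_cells, cfg.n_train_bulks, cfg.cells_per_bulk, cfg.seed, leaves=leaves
    )
    bulks_test, truth_test = [], []
    for batch in range(cfg.test_batches):
        bt, tt = make_pseudo_bulks(
            test_cells,
            cfg.test_batch_size,
            cfg.cells_per_bulk,
            cfg.seed + 10_000 + batch,
            leaves=leaves,
        )
        bt.columns = [f"b{batch}_{c}" for c in bt.columns]
        tt.columns = list(bt.columns)
        bulks_test.append(bt)
        truth_test.append(tt)
    return {
        "cells": cells,
        "train_cells": train_cells,
        "test_cells": test_cells,
        "bulks_train": bulks_train,
        "truth_train": truth_train,
        "bulks_test": bulks_test,
        "truth_test": truth_test,
    }
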