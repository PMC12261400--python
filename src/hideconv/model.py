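"""The hierarchical deconvolution estimator.

:class:`HideDeconvolver` proceeds top-down through a cell-type tree:

0. *Root fit* — learn gene weights for the coarsest level, solve the
   cone-constrained weighted least squares, calibrate each type with an
   affine rescale fitted on training mixtures, clip at zero and normalize
   every bulk's estimates to sum to one.
1. *Residual bulks* — for a parent type k, subtract the estimated
   contributions of all other parent-level types from the bulks and clip
   negative entries at zero.
2. *Child weighting* — learn gene weights on the residual bulks against the
   children's ground-truth proportions, using a reference containing the
   children only.
3. *Normalization* — calibrate each child row by the affine rescale fitted
   on the training estimates, clip at zero, then scale all children of a
   parent by a per-sample factor ξ so they sum exactly to the parent's
   estimate (ξ = 0 when the children's raw sum is zero, which also forces
   zero children whenever the parent is zero).

Steps 1–3 repeat level by level until the leaves, so coarse estimates are
final before fine ones are computed: training deeper levels never changes
upper-level output, and summing child estimates always reproduces the
parent exactly.

Two ablation variants are available through ``variant``: ``"flat"`` learns a
single root-style model at the leaf level (upper levels by summation), and
``"no_residual"`` keeps per-node weight learning but skips steps 1 and 3,
deconvolving every node's children from the original bulks without rescale
or ξ-normalization.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__
from .reference import expand_reference, restrict_genes, select_top_variance_genes, DEFAULT_TOP_K
from .solvers import TrainOptions, learn_gene_weights, solve_weighted_nnls
from .tree import CellTree, aggregate_proportions, parse_tree, tree_to_document

logger = logging.getLogger("hideconv")

__all__ = [
    "RescaleParams",
    "NodeModel",
    "HideDeconvolver",
    "fit_rescale",
    "apply_rescale_row",
    "residual_bulks",
    "apply_xi",
    "fit_hide",
]


# ---------------------------------------------------------------------------
# free operations (also used on their own in tests / downstream code)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RescaleParams:
    """Affine calibration of one cell type's estimate row: slope and intercept."""

    slope: float = 1.0
    intercept: float = 0.0


def fit_rescale(est_row, true_row) -> RescaleParams:
    """Ordinary least squares of truth on estimate (slope/intercept).

    Falls back to the identity when the estimate row has (near-)zero
    variance, where the regression is undefined.
    """
    e = np.asarray(est_row, dtype=float).ravel()
    t = np.asarray(true_row, dtype=float).ravel()
    var = e.var()
    if var <= 1e-300 or e.size < 2:
        return RescaleParams()
    slope = float(np.cov(e, t, bias=True)[0, 1] / var)
    intercept = float(t.mean() - slope * e.mean())
    return RescaleParams(slope, intercept)


def apply_rescale_row(row, params: RescaleParams) -> np.ndarray:
    """θ·row + Δ with negative values set to zero."""
    return np.maximum(params.slope * np.asarray(row, dtype=float) + params.intercept, 0.0)


def residual_bulks(Y, X_parent, C_parent, k: str):
    """Subtract all non-k parent contributions from the bulks; clip at zero.

    ``X_parent`` (genes x parent types) and ``C_parent`` (parent types x
    samples) must share the parent-level type set; ``k`` names the parent of
    interest. When k is the only parent-level type the bulks are returned
    unchanged.
    """
    if isinstance(X_parent, pd.DataFrame):
        types = list(X_parent.columns)
    elif isinstance(C_parent, pd.DataFrame):
        types = list(C_parent.index)
    else:
        raise ValueError("need labelled X_parent or C_parent to locate k")
    if k not in types:
        raise KeyError(f"{k!r} is not a parent-level cell type ({types!r})")
    others = [t for t in types if t != k]
    Ya = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if not others:
        out = Ya.copy()
    else:
        Xo = (X_parent[others] if isinstance(X_parent, pd.DataFrame) else
              np.asarray(X_parent, float)[:, [types.index(t) for t in others]])
        Co = (C_parent.loc[others] if isinstance(C_parent, pd.DataFrame) else
              np.asarray(C_parent, float)[[types.index(t) for t in others], :])
        out = np.clip(Ya - np.asarray(Xo, float) @ np.asarray(Co, float), 0.0, None)
    if isinstance(Y, pd.DataFrame):
        return pd.DataFrame(out, index=Y.index, columns=Y.columns)
    return out


def apply_xi(C_children, parent_row):
    """Scale child rows so each sample's children sum to the parent estimate.

    ξ_i = parent_i / Σ_k child_k,i, or 0 when the children's raw sum is 0
    (preventing division by zero and propagating absent parents to absent
    children). Inputs must be non-negative: clipping precedes this step.
    """
    C = C_children.to_numpy(dtype=float) if isinstance(C_children, pd.DataFrame) else np.asarray(C_children, float)
    parent = np.asarray(parent_row, dtype=float).ravel()
    if (C < 0).any() or (parent < 0).any():
        raise ValueError("negative proportions passed to xi normalization; clip first")
    sums = C.sum(axis=0)
    xi = np.where(sums > 0, np.divide(parent, np.where(sums > 0, sums, 1.0)), 0.0)
    out = C * xi[None, :]
    if isinstance(C_children, pd.DataFrame):
        return pd.DataFrame(out, index=C_children.index, columns=C_children.columns)
    return out


# ---------------------------------------------------------------------------
# per-node trained state
# ---------------------------------------------------------------------------

@dataclass
class NodeModel:
    """Trained state for one parent node (or the root level as a whole)."""

    node: str | None
    children: tuple[str, ...]
    weights: np.ndarray | None
    rescale: dict[str, RescaleParams]
    passthrough: bool = False


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class HideDeconvolver(BaseEstimator):
    """Hierarchical cell-type deconvolution with per-node learned gene weights.

    Parameters
    ----------
    tree
        :class:`~hideconv.tree.CellTree`, a nested document (dict), or a path
        to a tree JSON file.
    leaf_reference
        Consensus profiles, genes x leaf types (see
        :func:`hideconv.reference.build_reference`). Required for ``fit``.
    leaf_cell_counts
        Cells per leaf in the reference pool; weights the aggregation of leaf
        profiles into internal-node profiles. Equal weights when omitted.
    levels
        Coarse-to-fine level sequence (names declared in the tree document or
        explicit node lists). Defaults to the tree's declared levels, or one
        level per depth. The first level must be the tree's roots; training
        may stop above the leaves, in which case the finest fitted level is
        what :meth:`predict` returns.
    top_k_genes
        Number of highest-variance genes (computed across the leaf reference
        columns) retained as the shared gene index.
    variant
        ``"full"`` (the hierarchical algorithm), ``"flat"`` or
        ``"no_residual"`` (the two ablations).
    max_iters, tol, ridge_scale, constrained_gradient
        Gene-weight optimization schedule; see
        :class:`~hideconv.solvers.TrainOptions`.
    missing_gene_fraction
        Maximum tolerated fraction of model genes absent from a bulk matrix
        at prediction time (absent genes are zero-filled below it).
    random_state
        Accepted for pipeline compatibility; training is deterministic
        (full-batch descent from uniform weights), so it is recorded but
        unused.

    Attributes
    ----------
    gene_index_ : list of gene ids shared by all node models.
    levels_ : list of (name, node tuple), coarse to fine.
    level_references_ : dict level name -> genes x types reference (restricted).
    root_model_ : NodeModel for the first level.
    node_models_ : dict parent node -> NodeModel for each subdivided node.
    bulk_scale_ : target per-bulk total on the gene index (reference scale).
    """

    _FORMAT_VERSION = 1

    def __init__(
        self,
        tree=None,
        leaf_reference: pd.DataFrame | None = None,
        leaf_cell_counts: pd.Series | None = None,
        levels: Sequence[str | Sequence[str]] | None = None,
        top_k_genes: int = DEFAULT_TOP_K,
        variant: str = "full",
        max_iters: int = 300,
        tol: float = 1e-6,
        ridge_scale: float = 1e-8,
        constrained_gradient: bool = False,
        missing_gene_fraction: float = 0.05,
        random_state: int | None = None,
    ):
        self.tree = tree
        self.leaf_reference = leaf_reference
        self.leaf_cell_counts = leaf_cell_counts
        self.levels = levels
        self.top_k_genes = top_k_genes
        self.variant = variant
        self.max_iters = max_iters
        self.tol = tol
        self.ridge_scale = ridge_scale
        self.constrained_gradient = constrained_gradient
        self.missing_gene_fraction = missing_gene_fraction
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _resolve_tree(self) -> CellTree:
        if isinstance(self.tree, CellTree):
            return self.tree
        if isinstance(self.tree, (str, Path)):
            from .tree import load_tree

            return load_tree(self.tree)
        if isinstance(self.tree, (dict, list)):
            return parse_tree(self.tree)
        raise ValueError("tree must be a CellTree, a document or a path")

    def _train_options(self) -> TrainOptions:
        return TrainOptions(
            max_iters=self.max_iters,
            tol=self.tol,
            ridge_scale=self.ridge_scale,
            constrained_gradient=self.constrained_gradient,
        )

    def _normalize_bulks(self, Y: pd.DataFrame, *, fitting: bool) -> tuple[np.ndarray, list[str]]:
        """Samples x genes in -> genes x samples out, on the reference scale."""
        if not isinstance(Y, pd.DataFrame):
            raise ValueError("bulks must be a DataFrame with gene-named columns")
        present = [g for g in self.gene_index_ if g in Y.columns]
        missing = len(self.gene_index_) - len(present)
        frac = missing / len(self.gene_index_)
        if frac > self.missing_gene_fraction:
            raise ValueError(
                f"{missing} of {len(self.gene_index_)} model genes missing "
                f"({frac:.1%} > {self.missing_gene_fraction:.1%})"
            )
        if missing and not fitting:
            warnings.warn(
                f"{missing} model gene(s) absent from the bulks; zero-filled",
                RuntimeWarning,
                stacklevel=3,
            )
        mat = pd.DataFrame(0.0, index=list(Y.index), columns=list(self.gene_index_))
        mat[present] = Y[present].astype(float)
        values = mat.to_numpy().T  # genes x samples
        if (values < 0).any():
            raise ValueError("bulks contain negative entries")
        sums = values.sum(axis=0)
        scale = np.where(sums > 0, self.bulk_scale_ / np.where(sums > 0, sums, 1.0), 0.0)
        return values * scale[None, :], list(Y.index)

    @staticmethod
    def _normalize_columns(C: np.ndarray) -> np.ndarray:
        """Column-normalize to sum one; empty columns become uniform."""
        sums = C.sum(axis=0)
        out = np.empty_like(C)
        ok = sums > 0
        out[:, ok] = C[:, ok] / sums[ok]
        if (~ok).any():
            logger.warning("%d bulk(s) with all-zero estimates; set uniform", int((~ok).sum()))
            out[:, ~ok] = 1.0 / C.shape[0]
        return out

    def _fit_level_model(
        self, X: np.ndarray, Yn: np.ndarray, C_truth: np.ndarray, types: Sequence[str]
    ) -> tuple[NodeModel, np.ndarray]:
        """Root-style fit: weights, rescale, clip, per-bulk normalization."""
        if len(types) == 1:
            model = NodeModel(None, tuple(types), None, {types[0]: RescaleParams()}, True)
            return model, np.ones((1, Yn.shape[1]))
        g, trace = learn_gene_weights(X, Yn, C_truth, self._train_options())
        logger.info(
            "level fit over %d types: loss %.4f -> %.4f (%d steps)",
            len(types), trace[0], trace[-1], len(trace) - 1,
        )
        raw = solve_weighted_nnls(X, Yn, g)
        rescale = {}
        rescaled = np.empty_like(raw)
        for j, t in enumerate(types):
            rescale[t] = fit_rescale(raw[j], C_truth[j])
            rescaled[j] = apply_rescale_row(raw[j], rescale[t])
        final = self._normalize_columns(rescaled)
        return NodeModel(None, tuple(types), g, rescale), final

    def _predict_level_model(self, model: NodeModel, X: np.ndarray, Yn: np.ndarray) -> np.ndarray:
        if model.passthrough:
            return np.ones((1, Yn.shape[1]))
        raw = solve_weighted_nnls(X, Yn, model.weights)
        rescaled = np.empty_like(raw)
        for j, t in enumerate(model.children):
            rescaled[j] = apply_rescale_row(raw[j], model.rescale[t])
        return self._normalize_columns(rescaled)

    def _children_at(self, node: str, level_nodes: Sequence[str]) -> list[str]:
        return [v for v in level_nodes if self.tree_.is_ancestor_or_self(node, v)]

    # -- fitting ---------------------------------------------------------

    def fit(self, Y: pd.DataFrame, C: pd.DataFrame):
        """Train on bulks of known composition.

        Parameters
        ----------
        Y
            Training bulks, samples x genes (columns are gene ids).
        C
            Ground-truth proportions, samples x leaf types. Coarser-level
            truths are aggregated internally through the tree.
        """
        self.tree_ = self._resolve_tree()
        self.levels_ = self.tree_.ordered_levels(self.levels)
        if set(self.levels_[0][1]) != set(self.tree_.roots):
            raise ValueError("the first level must be the tree's roots")
        if self.variant not in ("full", "flat", "no_residual"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.leaf_reference is None:
            raise ValueError("leaf_reference is required for fitting")
        leaf_ref = self.leaf_reference
        missing = sorted(set(self.tree_.leaves) - set(leaf_ref.columns))
        if missing:
            raise ValueError(f"leaf_reference lacks leaf columns: {missing!r}")

        self.gene_index_ = list(select_top_variance_genes(leaf_ref, self.top_k_genes))
        self.level_references_ = {
            name: restrict_genes(
                expand_reference(leaf_ref, self.tree_, nodes, self.leaf_cell_counts),
                self.gene_index_,
            )
            for name, nodes in self.levels_
        }
        root_name = self.levels_[0][0]
        self.bulk_scale_ = float(
            self.level_references_[root_name].to_numpy().sum(axis=0).mean()
        )

        # leaf truth -> per-level truth, types x samples in level order
        if not isinstance(C, pd.DataFrame):
            raise ValueError("C must be a DataFrame, samples x leaf types")
        C_leafT = C.T  # leaves x samples
        truth_levels: dict[str, np.ndarray] = {}
        for name, nodes in self.levels_:
            truth_levels[name] = aggregate_proportions(
                C_leafT, self.tree_, nodes
            ).to_numpy()

        Yn, sample_ids = self._normalize_bulks(Y, fitting=True)
        if Yn.shape[1] != C.shape[0] or list(Y.index) != list(C.index):
            raise ValueError("Y and C must cover the same samples in the same order")

        self.node_models_ = {}
        if self.variant == "flat":
            if set(self.levels_[-1][1]) != set(self.tree_.leaves):
                raise ValueError("the flat variant requires the finest level to be the leaves")
            name, nodes = self.levels_[-1]
            Xl = self.level_references_[name].to_numpy()
            self.root_model_, _ = self._fit_level_model(
                Xl, Yn, truth_levels[name], nodes
            )
            return self

        # step 0: the root level
        name0, nodes0 = self.levels_[0]
        X0 = self.level_references_[name0].to_numpy()
        self.root_model_, C_prev = self._fit_level_model(X0, Yn, truth_levels[name0], nodes0)

        prev_name, prev_nodes = name0, nodes0
        for name, nodes in self.levels_[1:]:
            C_next = np.zeros((len(nodes), Yn.shape[1]))
            X_prev = self.level_references_[prev_name].to_numpy()
            X_here = self.level_references_[name].to_numpy()
            pos = {v: i for i, v in enumerate(nodes)}
            for ki, k in enumerate(prev_nodes):
                kids = self._children_at(k, nodes)
                rows = [pos[v] for v in kids]
                if len(kids) == 1:
                    # pass-through or single-child: the child inherits the
                    # parent's estimates exactly (xi would force this anyway)
                    self.node_models_[k] = NodeModel(
                        k, tuple(kids), None, {kids[0]: RescaleParams()}, True
                    )
                    C_next[rows[0]] = C_prev[ki]
                    continue
                try:
                    C_next[rows] = self._fit_node(
                        k, ki, kids, rows, X_prev, X_here, Yn, C_prev,
                        truth_levels[name],
                    )
                except Exception as err:
                    raise RuntimeError(f"training failed at node {k!r}: {err}") from err
            prev_name, prev_nodes, C_prev = name, nodes, C_next
        return self

    def _fit_node(
        self, k, ki, kids, rows, X_prev, X_here, Yn, C_prev, C_truth_level
    ) -> np.ndarray:
        """Steps 1-3 for one parent node on the training bulks."""
        if self.variant == "no_residual":
            Yk = Yn
        else:
            others = [i for i in range(C_prev.shape[0]) if i != ki]
            Yk = np.clip(Yn - X_prev[:, others] @ C_prev[others], 0.0, None)
        Xk = X_here[:, rows]
        Ck_truth = C_truth_level[rows]
        g, trace = learn_gene_weights(Xk, Yk, Ck_truth, self._train_options())
        logger.info(
            "node %r (%d children): loss %.4f -> %.4f (%d steps)",
            k, len(kids), trace[0], trace[-1], len(trace) - 1,
        )
        raw = solve_weighted_nnls(Xk, Yk, g)
        rescale = {}
        for j, t in enumerate(kids):
            if Ck_truth[j].var() == 0:
                logger.warning(
                    "child %r has constant training truth; identity rescale", t
                )
            rescale[t] = fit_rescale(raw[j], Ck_truth[j])
        self.node_models_[k] = NodeModel(k, tuple(kids), g, rescale)
        if self.variant == "no_residual":
            return raw
        rescaled = np.stack(
            [apply_rescale_row(raw[j], rescale[t]) for j, t in enumerate(kids)]
        )
        return apply_xi(rescaled, C_prev[ki])

    # -- prediction ------------------------------------------------------

    def predict_levels(self, Y: pd.DataFrame) -> dict[str, pd.DataFrame]:
        """Per-level proportion tables (samples x types), coarse to fine."""
        self._check_fitted()
        Yn, sample_ids = self._normalize_bulks(Y, fitting=False)
        arrays = self._forward(Yn)
        return {
            name: pd.DataFrame(arrays[name].T, index=sample_ids, columns=list(nodes))
            for name, nodes in self.levels_
        }

    def predict(self, Y: pd.DataFrame) -> np.ndarray:
        """Proportions at the finest fitted level (samples x types)."""
        name = self.levels_[-1][0]
        return self.predict_levels(Y)[name].to_numpy()

    def _forward(self, Yn: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.variant == "flat":
            name, nodes = self.levels_[-1]
            Xl = self.level_references_[name].to_numpy()
            leaf = self._predict_level_model(self.root_model_, Xl, Yn)
            leafT = pd.DataFrame(leaf, index=list(nodes))
            for lname, lnodes in self.levels_:
                if lnodes == nodes:
                    out[lname] = leaf
                else:
                    out[lname] = aggregate_proportions(leafT, self.tree_, lnodes).to_numpy()
            return out

        name0, nodes0 = self.levels_[0]
        X0 = self.level_references_[name0].to_numpy()
        C_prev = self._predict_level_model(self.root_model_, X0, Yn)
        out[name0] = C_prev
        prev_name, prev_nodes = name0, nodes0
        for name, nodes in self.levels_[1:]:
            C_next = np.zeros((len(nodes), Yn.shape[1]))
            X_prev = self.level_references_[prev_name].to_numpy()
            X_here = self.level_references_[name].to_numpy()
            pos = {v: i for i, v in enumerate(nodes)}
            for ki, k in enumerate(prev_nodes):
                model = self.node_models_[k]
                rows = [pos[v] for v in model.children]
                if model.passthrough:
                    C_next[rows[0]] = C_prev[ki]
                    continue
                if self.variant == "no_residual":
                    Yk = Yn
                else:
                    others = [i for i in range(C_prev.shape[0]) if i != ki]
                    Yk = np.clip(Yn - X_prev[:, others] @ C_prev[others], 0.0, None)
                raw = solve_weighted_nnls(X_here[:, rows], Yk, model.weights)
                if self.variant == "no_residual":
                    C_next[rows] = raw
                    continue
                rescaled = np.stack(
                    [
                        apply_rescale_row(raw[j], model.rescale[t])
                        for j, t in enumerate(model.children)
                    ]
                )
                C_next[rows] = apply_xi(rescaled, C_prev[ki])
            out[name] = C_next
            prev_name, prev_nodes, C_prev = name, nodes, C_next
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "root_model_"):
            raise RuntimeError("this HideDeconvolver instance is not fitted yet")

    # -- persistence -----------------------------------------------------

    @staticmethod
    def _slug(name: str) -> str:
        return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower() or "node"

    def save(self, path: str | Path) -> None:
        """Write the fitted model as a plain-text bundle directory."""
        self._check_fitted()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "tree.json", "w", encoding="utf-8") as fh:
            json.dump(tree_to_document(self.tree_), fh, indent=1, sort_keys=True)
        (path / "gene_index.txt").write_text("\n".join(self.gene_index_) + "\n")
        levels_dir = path / "levels"
        levels_dir.mkdir(parents=True, exist_ok=True)
        for i, (name, nodes) in enumerate(self.levels_):
            ref = self.level_references_[name]
            ref.to_csv(levels_dir / f"{i:02d}_{self._slug(name)}.reference.tsv", sep="\t")

        def dump_node(model: NodeModel, node_dir: Path) -> None:
            node_dir.mkdir(parents=True, exist_ok=True)
            meta = {
                "node": model.node,
                "children": list(model.children),
                "passthrough": model.passthrough,
                "rescale": {
                    t: [p.slope, p.intercept] for t, p in model.rescale.items()
                },
            }
            with open(node_dir / "meta.json", "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)
            if model.weights is not None:
                pd.Series(model.weights, index=self.gene_index_, name="weight").to_csv(
                    node_dir / "weights.tsv", sep="\t", header=True
                )

        dump_node(self.root_model_, path / "root")
        node_dirs = {}
        for i, (node, model) in enumerate(sorted(self.node_models_.items())):
            rel = f"nodes/{i:02d}_{self._slug(node)}"
            node_dirs[node] = rel
            dump_node(model, path / rel)
        manifest = {
            "format_version": self._FORMAT_VERSION,
            "package_version": __version__,
            "variant": self.variant,
            "levels": [[name, list(nodes)] for name, nodes in self.levels_],
            "bulk_scale": self.bulk_scale_,
            "params": {
                "top_k_genes": self.top_k_genes,
                "max_iters": self.max_iters,
                "tol": self.tol,
                "ridge_scale": self.ridge_scale,
                "constrained_gradient": self.constrained_gradient,
                "missing_gene_fraction": self.missing_gene_fraction,
                "random_state": self.random_state,
            },
            "node_dirs": node_dirs,
        }
        with open(path / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "HideDeconvolver":
        """Reconstruct a fitted estimator from a bundle directory."""
        path = Path(path)
        with open(path / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        if manifest.get("format_version") != cls._FORMAT_VERSION:
            raise ValueError("unsupported model bundle format")
        with open(path / "tree.json", encoding="utf-8") as fh:
            tree = parse_tree(json.load(fh))
        est = cls(
            tree=tree,
            variant=manifest["variant"],
            **manifest["params"],
        )
        est.tree_ = tree
        est.levels_ = [(name, tuple(nodes)) for name, nodes in manifest["levels"]]
        est.gene_index_ = (path / "gene_index.txt").read_text().splitlines()
        est.bulk_scale_ = float(manifest["bulk_scale"])
        est.level_references_ = {}
        for i, (name, nodes) in enumerate(est.levels_):
            ref = pd.read_csv(
                path / "levels" / f"{i:02d}_{cls._slug(name)}.reference.tsv",
                sep="\t",
                index_col=0,
                float_precision="round_trip",
            )
            # canonical memory layout so reloaded models predict bit-identically
            est.level_references_[name] = pd.DataFrame(
                np.ascontiguousarray(ref.to_numpy(dtype=float)),
                index=ref.index,
                columns=ref.columns,
            )

        def load_node(node_dir: Path) -> NodeModel:
            with open(node_dir / "meta.json", encoding="utf-8") as fh:
                meta = json.load(fh)
            weights = None
            if (node_dir / "weights.tsv").exists():
                weights = pd.read_csv(
                    node_dir / "weights.tsv", sep="\t", index_col=0,
                    float_precision="round_trip",
                )["weight"].to_numpy()
            rescale = {
                t: RescaleParams(s, d) for t, (s, d) in meta["rescale"].items()
            }
            return NodeModel(
                meta["node"], tuple(meta["children"]), weights, rescale, meta["passthrough"]
            )

        est.root_model_ = load_node(path / "root")
        est.node_models_ = {
            node: load_node(path / rel) for node, rel in manifest["node_dirs"].items()
        }
        return est


def fit_hide(
    bulks: pd.DataFrame,
    leaf_truth: pd.DataFrame,
    tree,
    leaf_reference: pd.DataFrame,
    **params,
) -> HideDeconvolver:
    """Functional wrapper: bulks and truth in genes/types x samples orientation."""
    est = HideDeconvolver(tree=tree, leaf_reference=leaf_reference, **params)
    return est.fit(bulks.T, leaf_truth.T)
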