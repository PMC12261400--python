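"""Scoring predictions against ground truth and cross-level consistency.

Per-cell-type metrics over a set of mixtures:

* Pearson correlation between the true and estimated proportion rows
  (affine-invariant; undefined — reported missing — for constant rows);
* NMAE, the mean absolute error divided by the mean true proportion of the
  type (scale-invariant; a ``range`` normalizer is available as a switch);
* consistency correlation between two prediction routes for the same level
  (direct deconvolution vs. summing child predictions).

``benchmark_report`` runs models over test batches and tabulates per-batch
metrics plus level means, the machinery behind mean-over-batches summaries.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import CellTree, aggregate_proportions

__all__ = [
    "pearson_per_type",
    "nmae_per_type",
    "consistency_correlation",
    "benchmark_report",
    "summarize_report",
]


def _aligned(C_true: pd.DataFrame, C_est: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(C_true.index) != set(C_est.index) or set(C_true.columns) != set(C_est.columns):
        raise ValueError("truth and estimate must share cell types and samples")
    return C_true, C_est.loc[C_true.index, C_true.columns]


def pearson_per_type(C_true: pd.DataFrame, C_est: pd.DataFrame) -> pd.Series:
    """Sample Pearson correlation per cell-type row (NaN for constant rows)."""
    C_true, C_est = _aligned(C_true, C_est)
    if C_true.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    t = C_true.to_numpy(dtype=float)
    e = C_est.to_numpy(dtype=float)
    tc = t - t.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    nt = np.sqrt((tc * tc).sum(axis=1))
    ne = np.sqrt((ec * ec).sum(axis=1))
    ok = (nt > 0) & (ne > 0)
    r = np.full(t.shape[0], np.nan)
    r[ok] = (tc[ok] * ec[ok]).sum(axis=1) / (nt[ok] * ne[ok])
    return pd.Series(r, index=C_true.index, name="pearson")


def nmae_per_type(
    C_true: pd.DataFrame, C_est: pd.DataFrame, normalizer: str = "mean"
) -> pd.Series:
    """Normalized mean absolute error per cell type.

    ``mean``: MAE / mean true proportion; ``range``: MAE / (max - min of the
    true row). Rows with a zero normalizer are reported missing.
    """
    C_true, C_est = _aligned(C_true, C_est)
    t = C_true.to_numpy(dtype=float)
    e = C_est.to_numpy(dtype=float)
    mae = np.abs(e - t).mean(axis=1)
    if normalizer == "mean":
        denom = t.mean(axis=1)
    elif normalizer == "range":
        denom = t.max(axis=1) - t.min(axis=1)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    out = np.where(denom > 0, mae / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(out, index=C_true.index, name="nmae")


def consistency_correlation(
    est_direct: pd.DataFrame, est_summed: pd.DataFrame
) -> pd.Series:
    """Per-type Pearson between direct and summed-from-children predictions."""
    r = pearson_per_type(est_direct, est_summed)
    r.name = "consistency"
    return r


def benchmark_report(
    models: Mapping[str, object],
    test_batches: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    tree: CellTree,
    levels: Sequence[tuple[str, Sequence[str]]],
    normalizer: str = "mean",
) -> pd.DataFrame:
    """Score fitted models on test batches, per level and cell type.

    Parameters
    ----------
    models
        Name -> fitted estimator with ``predict_levels`` (samples x genes in).
    test_batches
        Sequence of ``(bulks, leaf_truth)`` in genes/leaves x samples
        orientation with matching sample ids.
    levels
        ``(name, nodes)`` pairs; truths are aggregated from the leaf truth.

    Returns
    -------
    Tidy table with columns model, batch, level, cell_type, pearson, nmae.
    Upper-level scores use the model's own tables from ``predict_levels``
    (for the hierarchical model these equal the summed leaf predictions by
    construction).
    """
    if not test_batches:
        raise ValueError("need at least one test batch")
    rows = []
    for name, model in models.items():
        for b, (bulks, truth_leaf) in enumerate(test_batches):
            pred = model.predict_levels(bulks.T)
            for level_name, nodes in levels:
                truth = aggregate_proportions(truth_leaf, tree, nodes)
                est = pred[level_name].T  # types x samples
                r = pearson_per_type(truth, est)
                n = nmae_per_type(truth, est, normalizer=normalizer)
                for t in truth.index:
                    rows.append(
                        {
                            "model": name,
                            "batch": b,
                            "level": level_name,
                            "cell_type": t,
                            "pearson": r[t],
                            "nmae": n[t],
                        }
                    )
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- sd across batches, per model/level/cell type, plus level means.

    Level means average the per-type means over exactly the level's types,
    skipping degenerate (missing) entries; the ``n_missing`` column counts
    them. With a single batch the sd columns are absent.
    """
    per_type = (
        report.groupby(["model", "level", "cell_type"], sort=False)[["pearson", "nmae"]]
        .agg(["mean", "std"])
    )
    per_type.columns = ["_".join(c) for c in per_type.columns]
    n_batches = report["batch"].nunique()
    if n_batches < 2:
        per_type = per_type[[c for c in per_type.columns if not c.endswith("_std")]]
    level_rows = []
    for (model, level), sub in report.groupby(["model", "level"], sort=False):
        by_type = sub.groupby("cell_type", sort=False)[["pearson", "nmae"]].mean()
        level_rows.append(
            {
                "model": model,
                "level": level,
                "pearson_mean": by_type["pearson"].mean(skipna=True),
                "nmae_mean": by_type["nmae"].mean(skipna=True),
                "n_missing": int(by_type["pearson"].isna().sum()),
            }
        )
    levels_df = pd.DataFrame(level_rows).set_index(["model", "level"])
    return per_type, levels_df
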