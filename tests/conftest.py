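"""Shared fixtures: a seeded desk-scale hierarchical benchmark.

The benchmark simulates an annotated single-cell pool over the packaged
three-level synthetic tree, builds pseudo-bulk training mixtures and two
test batches, and trains the full hierarchical model plus both ablation
variants once per session.
"""

from __future__ import annotations

import pytest

import hideconv as hc

BENCH_SEED = 7


@pytest.fixture(scope="session")
def bench_data():
    cfg = hc.SimConfig(
        tree=hc.benchmark_tree(),
        genes=1000,
        cells_per_leaf=150,
        n_train_bulks=2000,
        test_batches=2,
        test_batch_size=400,
        seed=BENCH_SEED,
    )
    data = hc.simulate_dataset(cfg)
    data["cfg"] = cfg
    data["tree"] = cfg.tree
    data["leaf_ref"] = hc.build_reference(data["train_cells"], cfg.tree, cfg.tree.leaves)
    data["cell_counts"] = hc.leaf_cell_counts(data["train_cells"].labels, cfg.tree.leaves)
    return data


def train_variant(data, variant: str, **overrides) -> hc.HideDeconvolver:
    params = dict(
        tree=data["tree"],
        leaf_reference=data["leaf_ref"],
        leaf_cell_counts=data["cell_counts"],
        top_k_genes=500,
        variant=variant,
        max_iters=150,
    )
    params.update(overrides)
    est = hc.HideDeconvolver(**params)
    est.fit(data["bulks_train"].T, data["truth_train"].T)
    return est


@pytest.fixture(scope="session")
def bench_models(bench_data):
    return {v: train_variant(bench_data, v) for v in ("full", "flat", "no_residual")}


@pytest.fixture(scope="session")
def tiny_sim():
    """A very small simulated dataset for fast unit tests."""
    cfg = hc.SimConfig(
        tree=hc.benchmark_tree(),
        genes=300,
        cells_per_leaf=40,
        n_train_bulks=150,
        cells_per_bulk=50,
        test_batches=1,
        test_batch_size=60,
        seed=5,
    )
    data = hc.simulate_dataset(cfg)
    data["cfg"] = cfg
    data["tree"] = cfg.tree
    return data
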