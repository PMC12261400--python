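"""Synthetic single-cell generation, splitting, and pseudo-bulk construction."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import hideconv as hc
from hideconv.simulate import SimConfig, benchmark_tree, make_pseudo_bulks, simulate_cells, split_train_test
from hideconv.tree import parse_tree


def _small_cfg(**overrides):
    base = dict(
        tree=parse_tree(
            [
                {"name": "X", "children": [{"name": "X1"}, {"name": "X2"}]},
                {"name": "Y", "children": [{"name": "Y1"}, {"name": "Y2"}]},
                {"name": "Z", "children": [{"name": "Z1"}, {"name": "Z2"}]},
            ]
        ),
        genes=120,
        cells_per_leaf=50,
        seed=2,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestSimulateCells:
    def test_cell_count_and_labels_follow_config(self):
        cells = simulate_cells(_small_cfg())
        assert cells.counts.shape == (120, 300)
        assert set(cells.labels) == {"X1", "X2", "Y1", "Y2", "Z1", "Z2"}
        assert (cells.labels.value_counts() == 50).all()
        assert (cells.counts.to_numpy() >= 0).all()
        assert np.array_equal(cells.counts.to_numpy(), cells.counts.to_numpy().round())

    def test_same_seed_is_bit_identical(self):
        a = simulate_cells(_small_cfg())
        b = simulate_cells(_small_cfg())
        assert a.counts.equals(b.counts)
        assert a.labels.equals(b.labels)

    def test_zero_effect_size_makes_siblings_indistinguishable(self):
        """With no marker perturbation, per-gene means of sibling leaves pass
        a Bonferroni-corrected two-sample test at alpha = 0.01."""
        cfg = _small_cfg(genes=200, cells_per_leaf=150, effect_size=0.0, seed=9)
        cells = simulate_cells(cfg)
        a = cells.counts.loc[:, (cells.labels == "X1").to_numpy()].to_numpy()
        b = cells.counts.loc[:, (cells.labels == "X2").to_numpy()].to_numpy()
        _, p = scipy.stats.ttest_ind(a, b, axis=1)
        assert (p * cfg.genes > 0.01).all()

    def test_large_effect_separates_leaf_profiles(self):
        cfg = _small_cfg(effect_size=2.0, marker_fraction=0.1, dispersion=0.2, seed=4)
        cells = simulate_cells(cfg)
        ref = hc.build_reference(cells, cfg.tree, cfg.tree.leaves)
        corr = np.corrcoef(ref.to_numpy().T)
        off_diag = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert off_diag.max() < 1 - 1e-3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="marker_fraction"):
            _small_cfg(marker_fraction=1.5)
        with pytest.raises(ValueError, match="genes"):
            _small_cfg(genes=0)


class TestSplit:
    def test_even_counts_split_half_and_half(self):
        cells = simulate_cells(_small_cfg(cells_per_leaf=10))
        train, test = split_train_test(cells, seed=0)
        assert (train.labels.value_counts() == 5).all()
        assert (test.labels.value_counts() == 5).all()
        assert set(train.counts.columns).isdisjoint(test.counts.columns)
        assert len(train.counts.columns) + len(test.counts.columns) == 60

    def test_odd_counts_split_six_five(self):
        cells = simulate_cells(_small_cfg(cells_per_leaf=11))
        train, test = split_train_test(cells, seed=0)
        sizes = sorted([train.labels.value_counts()["X1"], test.labels.value_counts()["X1"]])
        assert sizes == [5, 6]

    def test_single_cell_leaf_rejected(self):
        cells = simulate_cells(_small_cfg(cells_per_leaf=5))
        one = hc.CellData(cells.counts.iloc[:, :1], cells.labels.iloc[:1])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(one, seed=0)

    def test_same_seed_same_split(self):
        cells = simulate_cells(_small_cfg())
        a_train, _ = split_train_test(cells, seed=3)
        b_train, _ = split_train_test(cells, seed=3)
        assert list(a_train.counts.columns) == list(b_train.counts.columns)


class TestPseudoBulks:
    def test_truth_is_exact_cell_fractions(self):
        cells = simulate_cells(_small_cfg())
        bulks, truth = make_pseudo_bulks(cells, n_bulks=25, cells_per_bulk=100, seed=1)
        assert bulks.shape == (120, 25)
        scaled = truth.to_numpy() * 100
        assert np.allclose(scaled, scaled.round(), atol=1e-9)
        assert np.allclose(truth.sum(axis=0), 1.0, atol=1e-12)

    def test_bulk_column_is_sum_of_drawn_cells(self):
        cells = simulate_cells(_small_cfg())
        bulks, truth, draws = make_pseudo_bulks(
            cells, n_bulks=5, cells_per_bulk=30, seed=1, return_indices=True
        )
        for b in range(5):
            manual = cells.counts.iloc[:, draws[b]].sum(axis=1)
            assert np.array_equal(bulks.iloc[:, b].to_numpy(), manual.to_numpy())
            drawn_labels = cells.labels.iloc[draws[b]].value_counts() / 30
            for leaf, frac in drawn_labels.items():
                assert truth.loc[leaf].iloc[b] == pytest.approx(frac)

    def test_study_defaults_match_training_design(self):
        cfg = SimConfig(tree=benchmark_tree())
        assert cfg.n_train_bulks == 20000
        assert cfg.cells_per_bulk == 100
        assert cfg.test_batches == 10
        assert cfg.test_batch_size == 1000

    def test_oversized_bulk_rejected(self):
        cells = simulate_cells(_small_cfg())
        with pytest.raises(ValueError, match="exceeds"):
            make_pseudo_bulks(cells, n_bulks=1, cells_per_bulk=10_000, seed=0)

    def test_aggregated_truth_still_sums_to_one(self, tiny_sim):
        truth = tiny_sim["truth_train"]
        tree = tiny_sim["tree"]
        for level in ("major", "minor"):
            agg = hc.aggregate_proportions(truth, tree, level)
            assert np.allclose(agg.sum(axis=0), 1.0, atol=1e-12)
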