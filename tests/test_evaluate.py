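"""Per-type metrics, consistency correlations and benchmark reporting."""

import numpy as np
import pandas as pd
import pytest

import hideconv as hc


def _frame(values, types=None, samples=None):
    values = np.asarray(values, dtype=float)
    types = types or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=types, columns=samples)


class TestPearson:
    def test_perfect_estimates_score_one(self):
        C = _frame(np.random.default_rng(0).uniform(size=(3, 6)))
        assert np.allclose(hc.pearson_per_type(C, C), 1.0)

    def test_affine_transformed_estimates_still_score_one(self):
        C = _frame(np.random.default_rng(1).uniform(size=(2, 8)))
        est = 3.0 * C + 0.2
        assert np.allclose(hc.pearson_per_type(C, est), 1.0)

    def test_reversed_row_scores_minus_one(self):
        truth = _frame([[1.0, 2.0, 3.0]])
        est = _frame([[3.0, 2.0, 1.0]])
        assert hc.pearson_per_type(truth, est).iloc[0] == pytest.approx(-1.0)

    def test_constant_truth_row_reported_missing(self):
        truth = _frame([[0.5, 0.5, 0.5], [0.1, 0.2, 0.3]])
        est = _frame([[0.4, 0.6, 0.5], [0.1, 0.2, 0.3]])
        r = hc.pearson_per_type(truth, est)
        assert np.isnan(r.iloc[0]) and r.iloc[1] == pytest.approx(1.0)

    def test_mismatched_types_rejected(self):
        with pytest.raises(ValueError, match="share"):
            hc.pearson_per_type(_frame([[1, 2, 3]]), _frame([[1, 2, 3]], types=["x"]))

    def test_invariant_to_joint_sample_permutation(self):
        rng = np.random.default_rng(4)
        truth = _frame(rng.uniform(size=(3, 10)))
        est = _frame(rng.uniform(size=(3, 10)))
        perm = rng.permutation(10)
        r1 = hc.pearson_per_type(truth, est)
        r2 = hc.pearson_per_type(truth.iloc[:, perm], est.iloc[:, perm])
        assert np.allclose(r1, r2)


class TestNMAE:
    def test_perfect_estimates_score_zero(self):
        C = _frame(np.random.default_rng(2).uniform(0.1, 1, size=(3, 5)))
        assert np.allclose(hc.nmae_per_type(C, C), 0.0)

    def test_known_arithmetic_case(self):
        truth = _frame([[0.1, 0.3]])
        est = _frame([[0.2, 0.4]])
        assert hc.nmae_per_type(truth, est).iloc[0] == pytest.approx(0.5)

    def test_invariant_to_joint_scaling(self):
        rng = np.random.default_rng(3)
        truth = _frame(rng.uniform(0.1, 1, size=(2, 7)))
        est = _frame(rng.uniform(0.1, 1, size=(2, 7)))
        a = hc.nmae_per_type(truth, est)
        b = hc.nmae_per_type(2 * truth, 2 * est)
        assert np.allclose(a, b)

    def test_range_normalizer_switch(self):
        truth = _frame([[0.0, 0.5]])
        est = _frame([[0.25, 0.25]])
        assert hc.nmae_per_type(truth, est, normalizer="range").iloc[0] == pytest.approx(0.5)

    def test_zero_truth_row_reported_missing(self):
        truth = _frame([[0.0, 0.0]])
        est = _frame([[0.1, 0.1]])
        assert np.isnan(hc.nmae_per_type(truth, est).iloc[0])


class TestConsistency:
    def test_identical_routes_score_one(self):
        C = _frame(np.random.default_rng(0).uniform(size=(4, 9)))
        assert np.allclose(hc.consistency_correlation(C, C), 1.0)

    def test_independent_routes_hover_near_zero(self):
        rng = np.random.default_rng(12)
        n = 400
        a = _frame(rng.uniform(size=(5, n)))
        b = _frame(rng.uniform(size=(5, n)))
        r = hc.consistency_correlation(a, b)
        assert np.abs(r).max() < 3 / np.sqrt(n)


class TestBenchmarkReport:
    def test_level_means_and_batch_sd(self, bench_models, bench_data):
        tree = bench_data["tree"]
        levels = tree.ordered_levels(None)
        batches = list(zip(bench_data["bulks_test"], bench_data["truth_test"]))
        report = hc.benchmark_report({"full": bench_models["full"]}, batches, tree, levels)
        per_type, level_means = hc.summarize_report(report)
        # level mean equals the arithmetic mean over exactly that level's types
        sub = report[(report["level"] == "major")]
        hand = sub.groupby("cell_type")["pearson"].mean().mean()
        assert level_means.loc[("full", "major"), "pearson_mean"] == pytest.approx(hand)
        assert "pearson_std" in per_type.columns  # two batches present

    def test_identical_batches_have_zero_sd(self, bench_models, bench_data):
        tree = bench_data["tree"]
        levels = tree.ordered_levels(None)
        batch = (bench_data["bulks_test"][0], bench_data["truth_test"][0])
        report = hc.benchmark_report(
            {"full": bench_models["full"]}, [batch, batch], tree, levels
        )
        per_type, _ = hc.summarize_report(report)
        assert np.allclose(per_type["pearson_std"].to_numpy(), 0.0)

    def test_single_batch_has_no_sd_column(self, bench_models, bench_data):
        tree = bench_data["tree"]
        levels = tree.ordered_levels(None)
        batch = (bench_data["bulks_test"][0], bench_data["truth_test"][0])
        report = hc.benchmark_report({"full": bench_models["full"]}, [batch], tree, levels)
        per_type, _ = hc.summarize_report(report)
        assert not any(c.endswith("_std") for c in per_type.columns)

    def test_no_batches_rejected(self, bench_models, bench_data):
        with pytest.raises(ValueError, match="at least one"):
            hc.benchmark_report({"full": bench_models["full"]}, [],
                                bench_data["tree"], [])
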