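"""Weighted NNLS, its closed-form relaxation, and gene-weight learning."""

import numpy as np
import pytest

import hideconv as hc
from hideconv.solvers import (
    GeneWeightDeconvolver,
    TrainOptions,
    correlation_loss,
    learn_gene_weights,
    solve_weighted_ls,
    solve_weighted_nnls,
)


def _uniform(p):
    return np.full(p, 1.0 / np.sqrt(p))


class TestWeightedNNLS:
    def test_identity_design_recovers_observations(self):
        X = np.eye(2)
        Y = np.array([[3.0], [1.0]])
        C = solve_weighted_nnls(X, Y, _uniform(2))
        assert np.allclose(C, [[3.0], [1.0]], atol=1e-10)

    def test_optimum_at_the_boundary_is_zero(self):
        X = np.array([[1.0], [0.0]])
        Y = np.array([[0.0], [5.0]])
        C = solve_weighted_nnls(X, Y, _uniform(2))
        assert np.allclose(C, [[0.0]], atol=1e-12)

    def test_matches_brute_force_grid(self):
        """An exhaustive grid over c in [0, 4]^2 confirms the minimizer (2, 1)."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([2.0, 1.0, 3.0])

        def sse(c1, c2):
            r = y[:, None, None] - X[:, 0, None, None] * c1 - X[:, 1, None, None] * c2
            return (r**2).sum(axis=0)

        coarse = np.arange(0.0, 4.0001, 0.01)
        g1, g2 = np.meshgrid(coarse, coarse, indexing="ij")
        i, j = np.unravel_index(np.argmin(sse(g1, g2)), g1.shape)
        fine1 = np.arange(max(coarse[i] - 0.05, 0), coarse[i] + 0.0501, 0.001)
        fine2 = np.arange(max(coarse[j] - 0.05, 0), coarse[j] + 0.0501, 0.001)
        f1, f2 = np.meshgrid(fine1, fine2, indexing="ij")
        i2, j2 = np.unravel_index(np.argmin(sse(f1, f2)), f1.shape)
        grid_optimum = np.array([fine1[i2], fine2[j2]])

        C = solve_weighted_nnls(X, y[:, None], _uniform(3))
        assert np.allclose(grid_optimum, [2.0, 1.0], atol=1e-3)
        assert np.allclose(C.ravel(), grid_optimum, atol=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_noise_free_mixtures_recovered_exactly(self, seed):
        """Y = XC with a well-conditioned reference is inverted to <= 1e-8."""
        rng = np.random.default_rng(seed)
        p, q, n = 60, 5, 12
        X = rng.uniform(0.5, 3.0, (p, q))
        C = rng.uniform(0.0, 1.0, (q, n))
        C[:, 0] = 0.0  # include an all-zero mixture
        Y = X @ C
        g = rng.uniform(0.2, 1.0, p)
        g /= np.linalg.norm(g)
        Chat = solve_weighted_nnls(X, Y, g)
        assert np.abs(Chat - C).max() <= 1e-8

    def test_rank_deficient_design_warns_and_solves(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # duplicated column
        Y = X @ np.array([[0.5], [0.25]])
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            C = solve_weighted_nnls(X, Y, _uniform(3))
        assert np.all(C >= 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            solve_weighted_nnls(np.eye(3), np.ones((2, 1)), _uniform(3))


class TestWeightedLS:
    def test_identity_design_returns_observations(self):
        Y = np.array([[3.0, 1.0], [2.0, 5.0]])
        C = solve_weighted_ls(np.eye(2), Y, _uniform(2))
        assert np.allclose(C, Y, atol=1e-6)

    def test_zero_weight_gene_is_ignored(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.5, 2.0, (4, 2))
        Y = rng.uniform(0.0, 5.0, (4, 6))
        g = np.array([1.0, 1.0, 1.0, 0.0])
        C1 = solve_weighted_ls(X, Y, g)
        Y2 = Y.copy()
        Y2[3] = 123.0  # only the zero-weight gene changes
        C2 = solve_weighted_ls(X, Y2, g)
        assert np.allclose(C1, C2)

    def test_matches_nnls_on_interior_optima(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            p, q, n = 30, 3, 8
            X = rng.uniform(0.5, 2.0, (p, q))
            C = rng.uniform(0.5, 1.5, (q, n))
            Y = X @ C
            g = rng.uniform(0.5, 1.5, p)
            ls = solve_weighted_ls(X, Y, g, ridge_scale=1e-12)
            nn = solve_weighted_nnls(X, Y, g)
            assert (ls > 0).all()  # interior: the cone constraint is inactive
            assert np.allclose(ls, nn, atol=1e-6)


class TestCorrelationLoss:
    def test_perfect_estimates_score_minus_q(self):
        rng = np.random.default_rng(2)
        C = rng.uniform(0.0, 1.0, (4, 20))
        loss = correlation_loss(_uniform(4), np.eye(4), C, C)
        assert loss == pytest.approx(-4.0, abs=1e-6)

    def test_constant_truth_row_is_excluded(self):
        rng = np.random.default_rng(2)
        C = rng.uniform(0.0, 1.0, (3, 15))
        C[2] = 0.4  # no variation across mixtures
        loss = correlation_loss(_uniform(3), np.eye(3), C, C)
        assert loss == pytest.approx(-2.0, abs=1e-6)

    def test_all_degenerate_rows_rejected(self):
        C = np.full((2, 10), 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            correlation_loss(_uniform(2), np.eye(2), C, C)

    def test_invariant_to_positive_rescaling_of_weights(self):
        rng = np.random.default_rng(5)
        p, q, n = 12, 3, 25
        X = rng.uniform(0.5, 2.0, (p, q))
        C = rng.uniform(0.0, 1.0, (q, n))
        Y = X @ C + rng.normal(0, 0.3, (p, n))
        g = rng.uniform(0.3, 1.2, p)
        for alpha in (0.1, 1.0, 7.5):
            assert correlation_loss(alpha * g, X, Y, C) == pytest.approx(
                correlation_loss(g, X, Y, C), abs=1e-9
            )


class TestWeightLearning:
    def _noisy_gene_instance(self, noise=1.2, seed=7, n=80):
        rng = np.random.default_rng(seed)
        x = np.array([5.0, 4.0])
        c = rng.uniform(0, 1, (1, n))
        Y = np.outer(x, c.ravel())
        Y[0] += rng.normal(0, 0.3, n)
        Y[1] += rng.normal(0, noise, n)
        return x[:, None], Y, c

    def test_learned_weights_have_unit_norm_and_monotone_loss(self):
        X, Y, C = self._noisy_gene_instance()
        g, trace = learn_gene_weights(X, Y, C)
        assert np.linalg.norm(g) == pytest.approx(1.0, abs=1e-9)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert trace[-1] <= trace[0]

    def test_informative_gene_outweighs_noise_gene_matching_grid_search(self):
        """The optimum over the unit circle, scanned at 0.1 degree resolution,
        agrees with gradient descent to within one degree."""
        X, Y, C = self._noisy_gene_instance()
        angles = np.arange(0.0, 90.0001, 0.1)
        losses = [
            correlation_loss(
                np.array([np.cos(np.radians(a)), np.sin(np.radians(a))]), X, Y, C
            )
            for a in angles
        ]
        grid_best = angles[int(np.argmin(losses))]
        g, _ = learn_gene_weights(X, Y, C, TrainOptions(max_iters=3000, tol=1e-13))
        learned = np.degrees(np.arctan2(abs(g[1]), abs(g[0])))
        assert abs(learned - grid_best) < 1.0
        assert abs(g[0]) > abs(g[1])

    def test_constrained_gradient_path_agrees_on_small_instance(self):
        X, Y, C = self._noisy_gene_instance()
        g_un, _ = learn_gene_weights(X, Y, C, TrainOptions(max_iters=500, tol=1e-10))
        g_con, trace = learn_gene_weights(
            X, Y, C, TrainOptions(max_iters=200, tol=1e-10, constrained_gradient=True)
        )
        a_un = np.degrees(np.arctan2(abs(g_un[1]), abs(g_un[0])))
        a_con = np.degrees(np.arctan2(abs(g_con[1]), abs(g_con[0])))
        assert abs(a_un - a_con) < 2.0
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_degenerate_data_rejected_before_iterating(self):
        C = np.full((2, 10), 0.3)
        Y = np.eye(2) @ C
        with pytest.raises(ValueError, match="degenerate"):
            learn_gene_weights(np.eye(2), Y, C)


class TestGeneWeightDeconvolver:
    def test_sklearn_style_fit_predict_round_trip(self):
        rng = np.random.default_rng(0)
        p, q, n = 40, 3, 60
        X = rng.uniform(0.5, 2.0, (p, q))
        C = rng.dirichlet(np.ones(q), size=n)  # samples x types
        Y = C @ X.T + rng.normal(0, 0.1, (n, p))
        est = GeneWeightDeconvolver(reference=X, max_iters=100)
        est.fit(Y, C)
        assert np.linalg.norm(est.weights_) == pytest.approx(1.0, abs=1e-9)
        pred = est.predict(Y)
        assert pred.shape == (n, q)
        r = np.corrcoef(pred[:, 0], C[:, 0])[0, 1]
        assert r > 0.95

    def test_get_set_params_round_trip(self):
        est = GeneWeightDeconvolver(max_iters=50)
        est.set_params(tol=1e-4)
        assert est.get_params()["tol"] == 1e-4
        with pytest.raises(ValueError, match="invalid parameter"):
            est.set_params(bogus=1)
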