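"""Weighted non-negative deconvolution and gene-weight learning.

The mixing model is Y = XC with reference profiles X (genes x types), bulks
Y (genes x samples) and non-negative proportions C (types x samples). The
weighted estimator solves, per bulk y,

    c(g) = argmin_{c >= 0} || diag(g) (y - Xc) ||^2 ,

and the per-gene weights g (unit l2 norm) are learned on training mixtures
of known composition by minimizing the negative sum of Pearson correlations
between true and estimated proportion rows. Inside the optimization the
non-negativity cone is relaxed to the differentiable closed form
(X' G X + eps I)^{-1} X' G Y with G = diag(g^2), so the loss gradient is
available analytically; the cone-constrained solver is used at inference
(and optionally during training via numerical gradients).

Effective weights enter as g^2, so the sign of g is immaterial and the unit
norm is a normalization, not a restriction: the loss is invariant to
positive rescaling of g.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

logger = logging.getLogger("hideconv")

__all__ = [
    "TrainOptions",
    "solve_weighted_nnls",
    "solve_weighted_ls",
    "correlation_loss",
    "learn_gene_weights",
    "GeneWeightDeconvolver",
]

_RIDGE_SCALE = 1e-8


@dataclass
class TrainOptions:
    """Gene-weight optimization schedule."""

    max_iters: int = 300
    tol: float = 1e-6
    ridge_scale: float = _RIDGE_SCALE
    constrained_gradient: bool = False
    step_init: float = 1.0
    max_backtracks: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iters < 1 or self.max_backtracks < 1:
            raise ValueError("iteration counts must be positive")
        if self.tol <= 0 or self.ridge_scale < 0 or self.step_init <= 0:
            raise ValueError("tol and step_init must be positive, ridge_scale >= 0")


def _as_array(a) -> np.ndarray:
    # C-contiguous canonical layout keeps BLAS summation order, and hence
    # results, bit-reproducible across differently stored but equal inputs
    values = a.to_numpy(dtype=float) if isinstance(a, pd.DataFrame) else np.asarray(a, dtype=float)
    return np.ascontiguousarray(values)


def _wrap_like(values: np.ndarray, X, Y):
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        return pd.DataFrame(values, index=list(X.columns), columns=list(Y.columns))
    return values


def _weighted_grams(X: np.ndarray, Y: np.ndarray, g: np.ndarray):
    w = g * g
    Xw = X * w[:, None]
    return Xw.T @ X, Xw.T @ Y


def solve_weighted_nnls(X, Y, g, ridge_scale: float = 0.0):
    """Cone-constrained weighted least squares, solved per bulk column.

    The p-row problem is compressed to q dimensions through the Cholesky
    factor of X' G X (identical minimizer); a rank-deficient weighted design
    is handled by adding a ridge jitter, with a warning.
    """
    Xa, Ya, ga = _as_array(X), _as_array(Y), np.asarray(g, dtype=float).ravel()
    if Xa.shape[0] != Ya.shape[0] or Xa.shape[0] != ga.shape[0]:
        raise ValueError(
            f"dimension mismatch: X {Xa.shape}, Y {Ya.shape}, g {ga.shape}"
        )
    q = Xa.shape[1]
    M, F = _weighted_grams(Xa, Ya, ga)
    eps = ridge_scale * np.trace(M) / max(q, 1)
    if eps > 0:
        M = M + eps * np.eye(q)
    try:
        L = scipy.linalg.cholesky(M, lower=True)
    except scipy.linalg.LinAlgError:
        jitter = _RIDGE_SCALE * max(np.trace(M) / max(q, 1), 1.0)
        warnings.warn(
            "weighted design is rank deficient; solving with ridge jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        L = scipy.linalg.cholesky(M + jitter * np.eye(q), lower=True)
    B = scipy.linalg.solve_triangular(L, F, lower=True)
    A = L.T
    C = np.empty((q, Ya.shape[1]))
    for i in range(Ya.shape[1]):
        C[:, i], _ = scipy.optimize.nnls(A, B[:, i])
    return _wrap_like(C, X, Y)


def solve_weighted_ls(X, Y, g, ridge_scale: float = _RIDGE_SCALE):
    """Unconstrained weighted least squares, closed form with ridge jitter."""
    Xa, Ya, ga = _as_array(X), _as_array(Y), np.asarray(g, dtype=float).ravel()
    if Xa.shape[0] != Ya.shape[0] or Xa.shape[0] != ga.shape[0]:
        raise ValueError(
            f"dimension mismatch: X {Xa.shape}, Y {Ya.shape}, g {ga.shape}"
        )
    q = Xa.shape[1]
    M, F = _weighted_grams(Xa, Ya, ga)
    eps = ridge_scale * np.trace(M) / max(q, 1)
    A = M + max(eps, np.finfo(float).tiny) * np.eye(q)
    C = scipy.linalg.solve(A, F, assume_a="pos")
    return _wrap_like(C, X, Y)


def _row_correlations(C: np.ndarray, Chat: np.ndarray):
    """Per-row Pearson r plus validity mask (rows with variance on both sides)."""
    Cc = C - C.mean(axis=1, keepdims=True)
    Hc = Chat - Chat.mean(axis=1, keepdims=True)
    nc = np.sqrt((Cc * Cc).sum(axis=1))
    nh = np.sqrt((Hc * Hc).sum(axis=1))
    valid = (nc > 0) & (nh > 0)
    r = np.zeros(C.shape[0])
    r[valid] = (Cc[valid] * Hc[valid]).sum(axis=1) / (nc[valid] * nh[valid])
    return r, valid, (Cc, Hc, nc, nh)


def correlation_loss(
    g,
    X,
    Y_train,
    C_train,
    constrained: bool = False,
    ridge_scale: float = _RIDGE_SCALE,
) -> float:
    """Negative sum of per-type Pearson correlations between truth and estimate.

    Rows whose ground truth or estimate is constant across mixtures are
    excluded (Pearson is undefined there); an error is raised when no row
    remains.
    """
    Xa, Ya, Ca = _as_array(X), _as_array(Y_train), _as_array(C_train)
    if Ca.shape[0] != Xa.shape[1] or Ca.shape[1] != Ya.shape[1]:
        raise ValueError(f"C_train shape {Ca.shape} does not match X/Y")
    if Ya.shape[1] < 3:
        raise ValueError("need at least 3 training mixtures for a correlation loss")
    solver = solve_weighted_nnls if constrained else solve_weighted_ls
    Chat = _as_array(solver(Xa, Ya, np.asarray(g, float).ravel(), ridge_scale=ridge_scale))
    r, valid, _ = _row_correlations(Ca, Chat)
    if not valid.any():
        raise ValueError("all cell-type rows are degenerate; correlation loss undefined")
    if not valid.all():
        logger.debug("correlation loss: %d degenerate row(s) excluded", int((~valid).sum()))
    return float(-r[valid].sum())


def _loss_and_grad(g, Xa, Ya, Ca, ridge_scale):
    """Analytic loss and gradient through the unconstrained closed form."""
    q = Xa.shape[1]
    M, F = _weighted_grams(Xa, Ya, g)
    eps = ridge_scale * np.trace(M) / max(q, 1)
    A = M + max(eps, np.finfo(float).tiny) * np.eye(q)
    try:
        Chat = scipy.linalg.solve(A, F, assume_a="pos")
    except scipy.linalg.LinAlgError:
        return np.inf, None
    r, valid, (Cc, Hc, nc, nh) = _row_correlations(Ca, Chat)
    if not valid.any():
        return np.inf, None
    loss = -r[valid].sum()
    # dL/dChat, row-wise; degenerate rows contribute nothing this iteration
    G = np.zeros_like(Chat)
    v = valid
    G[v] = -(Cc[v] / (nc[v] * nh[v])[:, None] - (r[v] / (nh[v] ** 2))[:, None] * Hc[v])
    V = scipy.linalg.solve(A, G, assume_a="pos")
    R = Ya - Xa @ Chat
    grad_w = ((Xa @ V) * R).sum(axis=1)
    return float(loss), 2.0 * g * grad_w


def _numeric_grad(g, loss_fn, h=1e-6):
    grad = np.zeros_like(g)
    for i in range(g.size):
        gp, gm = g.copy(), g.copy()
        gp[i] += h
        gm[i] -= h
        grad[i] = (loss_fn(gp) - loss_fn(gm)) / (2 * h)
    return grad


def learn_gene_weights(X, Y_train, C_train, options: TrainOptions | None = None):
    """Learn unit-norm gene weights by projected gradient descent.

    Starts from uniform weights, backtracks until the loss decreases, and
    renormalizes to the unit sphere after every accepted step, so the
    accepted-loss trace is monotone non-increasing and never worse than the
    uniform-weight loss.

    Returns ``(g, trace)`` with ``trace`` the list of accepted losses
    (uniform-weight loss first).
    """
    opts = options or TrainOptions()
    Xa, Ya, Ca = _as_array(X), _as_array(Y_train), _as_array(C_train)
    if Ca.shape[0] != Xa.shape[1] or Ca.shape[1] != Ya.shape[1]:
        raise ValueError(f"C_train shape {Ca.shape} does not match X/Y")
    p = Xa.shape[0]
    g = np.full(p, 1.0 / np.sqrt(p))

    if opts.constrained_gradient:
        def loss_fn(gv):
            try:
                return correlation_loss(
                    gv, Xa, Ya, Ca, constrained=True, ridge_scale=opts.ridge_scale
                )
            except ValueError:
                return np.inf

        def evaluate(gv):
            ls = loss_fn(gv)
            if not np.isfinite(ls):
                return ls, None
            return ls, _numeric_grad(gv, loss_fn)
    else:
        def evaluate(gv):
            return _loss_and_grad(gv, Xa, Ya, Ca, opts.ridge_scale)

    loss, grad = evaluate(g)
    if not np.isfinite(loss):
        raise ValueError("correlation loss is non-finite for uniform weights; degenerate data")
    trace = [loss]
    eta = opts.step_init
    for _ in range(opts.max_iters):
        direction = grad - (grad @ g) * g  # tangent to the unit sphere
        dn = np.linalg.norm(direction)
        if dn < 1e-14:
            break
        accepted = False
        for _ in range(opts.max_backtracks):
            cand = g - eta * direction
            cand /= np.linalg.norm(cand)
            cand_loss, cand_grad = evaluate(cand)
            if np.isfinite(cand_loss) and cand_loss < loss - 1e-15:
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            break
        rel = (loss - cand_loss) / max(abs(loss), 1e-12)
        g, loss, grad = cand, cand_loss, cand_grad
        trace.append(loss)
        eta *= 2.0
        if rel < opts.tol:
            break
    return g, trace


class GeneWeightDeconvolver:
    """Single-level deconvolution with learned gene weights (sklearn-style).

    A thin estimator over :func:`learn_gene_weights` /
    :func:`solve_weighted_nnls` for a fixed reference matrix, usable inside
    sklearn pipelines and model selection. The hierarchical estimator in
    :mod:`hideconv.model` runs one of these, in spirit, at every tree node.

    Parameters
    ----------
    reference
        Reference profiles, genes x cell types (DataFrame or array).
    max_iters, tol, ridge_scale, constrained_gradient
        See :class:`TrainOptions`.

    Attributes
    ----------
    weights_ : learned unit-norm gene weights.
    loss_trace_ : accepted correlation-loss values, uniform weights first.
    """

    def __init__(
        self,
        reference=None,
        max_iters: int = 300,
        tol: float = 1e-6,
        ridge_scale: float = _RIDGE_SCALE,
        constrained_gradient: bool = False,
    ):
        self.reference = reference
        self.max_iters = max_iters
        self.tol = tol
        self.ridge_scale = ridge_scale
        self.constrained_gradient = constrained_gradient

    def get_params(self, deep: bool = True) -> dict:
        return {
            "reference": self.reference,
            "max_iters": self.max_iters,
            "tol": self.tol,
            "ridge_scale": self.ridge_scale,
            "constrained_gradient": self.constrained_gradient,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, Y, C):
        """Learn gene weights from bulks Y (samples x genes) and truth C (samples x types)."""
        Xa = _as_array(self.reference)
        Ya = _as_array(Y).T
        Ca = _as_array(C).T
        opts = TrainOptions(
            max_iters=self.max_iters,
            tol=self.tol,
            ridge_scale=self.ridge_scale,
            constrained_gradient=self.constrained_gradient,
        )
        self.weights_, self.loss_trace_ = learn_gene_weights(Xa, Ya, Ca, opts)
        return self

    def predict(self, Y):
        """Cone-constrained proportion estimates (samples x types)."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("this GeneWeightDeconvolver instance is not fitted yet")
        return _as_array(solve_weighted_nnls(_as_array(self.reference), _as_array(Y).T, self.weights_)).T
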