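# Methods

## Model and assumptions

Bulk expression is assumed to be a non-negative linear mixture of cell-type
consensus profiles, Y = XC. The estimator solves a per-gene-weighted
constrained least squares per bulk; the weights g, constrained to the unit
l2 sphere, are learned on training mixtures of known composition by
minimizing L(g) = −Σ_j cor(C_j,·, Ĉ_j,·(g)). Because the effective weights
enter as g², the sign of g carries no information and the loss is invariant
to positive rescaling of g; the unit norm is therefore a normalization, not
a restriction, and we assert it numerically in the tests.

The hierarchy is a forest of uniquely named nodes with explicit *levels*:
antichains that cover every leaf exactly once. A population that is not
subdivided at some resolution stands for itself at that level, so no
phantom nodes are needed for unbalanced trees. Depth is unlimited; the
packaged breast hierarchy (9/13/34 types) and the synthetic benchmark tree
(4/7/11) are both three-level instances.

The hierarchical fit proceeds level by level, coarse to fine (breadth
first), so a node's parent totals are final before its children are
normalized. Residual bulks for a parent k subtract the *finalized*
parent-level estimates of all other parent types and clip at zero; child
estimates are calibrated by an affine rescale (OLS of truth on estimate,
fitted on training estimates and frozen), clipped, and scaled per sample by
ξ = parent / Σ children (ξ = 0 when the raw child sum is zero). Two
consequences are load-bearing and tested: child estimates sum to the parent
estimate to ~1e-10 at every depth (so leaf columns sum to 1 by telescoping
from the root's normalization), and fitting deeper levels cannot change
upper-level output bit for bit.

Residual training bulks are built from the model's own training-set
estimates, not from ground truth: deployment has no truth available, and
training should match deployment conditions.

## Scale handling

References are means of depth-normalized cell profiles (counts per 10k), so
a reference column sums to 10⁴ over all genes; pseudo-bulks are raw sums of
~100 cells. The residual step subtracts X·Ĉ with Ĉ on the proportion scale,
which is only meaningful if Y is on the reconstruction scale of X. The
model therefore rescales every bulk column, over its gene index, to the
mean column sum of the root reference before any solving (in both fit and
predict). After this step raw constrained estimates are approximately on
the proportion scale, the fitted rescale slopes sit near 1, and the
subtraction in the residual step removes the intended share of signal.
Per-type depth differences between cell types (which make normalized bulk
composition deviate from cell-count composition) are absorbed by the
affine rescale.

## Gene-weight optimization

Inside training the non-negativity cone is relaxed to the differentiable
closed form Ĉ = (XᵀΓX + εI)⁻¹XᵀΓY with Γ = diag(g²) and ε =
1e-8·trace(XᵀΓX)/q, which keeps the loss exactly invariant to rescaling of
g and gives the gradient in closed form (dL/dw_i = x_iᵀ A⁻¹ G r_i summed
over samples, w = g², with G the correlation-loss gradient in Ĉ). The
optimizer is projected gradient descent on the unit sphere with backtracking
line search: start from uniform weights g_i = 1/√p, halve the step until the
loss decreases, renormalize after every accepted step, double the step after
success; stop at relative loss change < 1e-6 (default) or `max_iters`.
Accepted losses are monotone non-increasing by construction, so the learned
weights are never worse than uniform on the training loss. A
`constrained_gradient` switch trains against the cone-constrained solver
with central finite differences instead — feasible for small gene panels
only, and it agrees with the relaxed path to within a degree on the
two-gene test instance.

At inference the cone-constrained problem is solved exactly per bulk by
compressing the p-row problem to q dimensions through the Cholesky factor
of XᵀΓX (an identical minimizer) and running active-set NNLS there. No
ridge is added on this path unless the weighted Gram matrix is rank
deficient, in which case a jitter of 1e-8·trace/q is added with a warning;
this keeps noise-free mixtures recoverable to ≤1e-8.

Degenerate correlation rows — zero variance in truth or in the estimate —
are dropped from the loss for that evaluation (Pearson is undefined there;
rare types can be truth-constant in small mixture sets) and the fit errors
out only if no valid row remains.

## Synthetic data generator

The generator emulates the study design end to end: a hierarchical
single-cell pool with known leaf labels, a stratified 50/50 train/test
split, and pseudo-bulks of `cells_per_bulk` (default 100) cells drawn
uniformly without replacement within a bulk, summed as raw counts, with the
drawn label counts as exact ground truth (entries are multiples of
1/cells_per_bulk; columns sum to 1). Default mixture counts are the full
study conditions (20 000 training bulks, 10 test batches of 1000).

Expression follows a hierarchical log-normal/negative-binomial model: each
tree node perturbs a random `marker_fraction` (default 0.05) of its
parent's log-mean profile by ±`effect_size` (default 1.0 natural-log units),
so sibling leaves are strongly correlated while distant types differ in
many genes — the regime in which hierarchical deconvolution is expected to
pay off. Counts are gamma–Poisson with dispersion 0.4 around a log-normally
varying library size (mean 1500, σ = 0.25). These defaults were chosen once
as a plausible desk-scale stand-in for an annotated tumor atlas. The
generator does **not** emulate platform/batch effects between single-cell
and bulk data, per-type cell-count imbalance of real atlases, or ambient
RNA; passing tests therefore demonstrate the correctness and internal
consistency of the algorithm under its own model class, not its accuracy on
real cross-platform data.

One integer seed drives independent sub-streams for cell simulation,
splitting and bulk drawing, so the entire pipeline (including saved model
bundles and written prediction tables) reproduces bit-identically.
Solver inputs are canonicalized to one memory layout before BLAS calls so
that reloaded models also predict bit-identically.

## Evaluation

Per-type Pearson and NMAE are computed row-wise over samples. NMAE is
MAE divided by the mean true proportion of the type (a `range` normalizer
is available); it is scale-invariant and matches the qualitative use of
NMAE in deconvolution benchmarking, but since competing definitions exist,
only orderings — not absolute NMAE values — should be compared across
software. Degenerate rows are reported missing and excluded from level
means, with a count of exclusions in the summary.

Ablation variants: `flat` learns a single leaf-level model (upper levels by
summation); `no_residual` keeps the root model and per-node weight learning
but skips the residual and normalization steps, deconvolving each node's
children from the original bulks. Ablation scoring aggregates the finest
predictions upward for all variants; the unnormalized variant's inflated
totals (every node's children absorb the whole bulk) are the expected
signature of removing those steps.

## Problem sizes and numerical choices

The packaged benchmark and the acceptance script run the pipeline at desk
scale — 1000–1500 genes (top 500–750 by reference variance), 11 leaf types,
150 cells per leaf, 2000 training mixtures, 400–500 test bulks — chosen as
the package's own default study size so a full train/predict/score cycle
completes in well under a minute. At full study scale (5000 genes,
20 000 mixtures, 34 leaves) the same code paths apply unchanged.

Other numerical policies: gene-variance ties break by input gene order;
a bulk whose estimates are all zero after clipping is set uniform at the
root level (with a warning) so per-sample normalization stays defined;
single-child and pass-through nodes bypass fitting entirely and inherit the
parent row (ξ would force this anyway); zero-control-mean genes get
rescale factor 1 with a warning rather than an infinite factor; prediction
tolerates up to 5% missing model genes (zero-filled, with a warning) and
errors above that.

## Known limitations

* Accuracy numbers on synthetic data are not comparable to numbers obtained
  on real single-cell compendia; only structural properties (consistency,
  conservation, ablation direction) transfer.
* The affine rescale is fitted on training estimates; under strong domain
  shift between training pseudo-bulks and real bulks it can miscalibrate —
  the gene-wise rescaling utilities mitigate but do not remove this.
* No background/hidden-content term: cell types absent from the reference
  inflate the estimates of the types present.
* Hierarchies are taken as given; the package does not infer them.
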