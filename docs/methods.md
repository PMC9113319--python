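# Methods

## Preprocessing and the extended matrix

Omic blocks arrive as samples × features matrices with shared sample IDs.
The pipeline is: **align** (reorder every block to the first block's
sample order; mismatched ID sets are an error listing the symmetric
difference) → **impute** (each missing entry replaced by its feature's
mean over observed samples; a fully missing feature is an error; the
missingness mask is kept for provenance) → **adjust** (optional:
least-squares residualization of every feature on an intercept plus the
covariate design, so residuals are exactly orthogonal to every
confounder column; categorical covariates are expanded to
treatment-coded indicators with the first level dropped; missing
covariate values are an error rather than silently imputed) →
**standardize and normalize** (each feature centered and scaled to unit
sample standard deviation, divisor n−1; each standardized block then
divided by its Frobenius norm).

Design choices worth stating:

- *Adjust before standardize.* Residualization acts on the original
  measurement scale, removing confounder main effects from every feature;
  standardization afterwards puts the residuals on a common scale.
- *Block Frobenius normalization* makes every block contribute equal
  total variance to the extended matrix regardless of its feature count —
  the usual motivation in multi-block factorization, preventing a
  million-feature layer from dominating a hundred-protein layer.
- *Constant features* (zero variance) are set to all zeros and flagged
  with a warning, not dropped, so the column → (block, feature) map stays
  aligned with the input.
- All standardization parameters (per-column mean/scale, per-block norm)
  are stored; `ExtendedMatrix.inverse_transform()` reproduces the imputed
  input to ~1e-10 relative error.

## The sparse SVD

Each factor solves the penalized rank-1 problem

    min_{u, ṽ}  ‖X − u ṽᵀ‖_F²  +  2 λ (α‖ṽ‖₁ + (1−α)/2 ‖ṽ‖₂²),   ‖u‖ = 1,

by alternating minimization: the ṽ-step is the elastic-net proximal map
applied to Xᵀu, the u-step is u = Xṽ/‖Xṽ‖. Both half-steps minimize the
joint objective exactly, so it is non-increasing across iterations
(`track_objective=True` records it; a property test asserts
monotonicity). Convergence is declared when the relative L2 change of
the normalized v falls below `tol` (default 1e-6; `max_iter` 1000, with
a warning and `converged=False` on exhaustion). Sparsity is imposed on
the feature side only; sample scores stay dense, since the package's
selection semantics concern features.

- *Initialization* is the leading dense singular pair of the current
  residual, computed by ARPACK with a fixed starting vector. This makes
  every decomposition deterministic without user seeding and means a
  zero-penalty fit reproduces the dense triplet immediately.
- *Degree parametrization.* A requested degree s is converted to the
  largest cutoff t whose support-restricted soft-threshold leaves exactly
  s nonzeros (λ = t/α). With distinct magnitudes this is the (s+1)-th
  largest |z| scaled by 1/α. Ties at the cutoff keep the tied entry with
  the smallest column index — the largest cutoff strictly below the
  smallest kept magnitude is used, so the count is exact and the result
  platform-independent. α = 0 with a degree is rejected (ridge cannot
  produce exact zeros).
- *Deflation.* Factors are extracted sequentially, subtracting d·u·vᵀ
  after each fit (in memory explicitly, out of core as a rank-1
  correction to the operator). Factors are reported in descending order
  of d; the largest-magnitude loading of each factor is flipped positive.

## Automatic degree tuning

For each factor, every candidate degree k on a grid (default: 20
log-spaced integers from 1 to P) is fit from the same dense
initialization and scored by

    BIC(k) = log(RSS_k / nP) + k · log(nP) / nP,   RSS_k = ‖X − d u vᵀ‖_F²,

the information criterion of the iterative-thresholding sparse-SVD
literature this implementation follows; the minimizing degree is
selected, with ties broken toward the smallest degree (parsimony). This
criterion form is an interpretation — it is the standard choice for
rank-1 residual selection, adopted here as the package's definition.

A *flat curve* — the log-RSS profile varies by less than 0.1 across the
whole grid — indicates a matrix with no sparse low-rank structure (e.g.
pure noise, where removing any rank-1 piece barely changes the fit); the
selected degree is then reported with a `FlatTuningCurveWarning`. The
0.1 margin is far below the log-RSS drop of any signal worth selecting
(a detectable spike moves it by ~0.5 or more) and far above the noise
profile's range (~0.03 at n·P = 5000).

## Out-of-core backend

`ChunkedMatrix` stores the extended matrix as a flat row-major float64
binary with a JSON header (shape, chunk size, column provenance). Row
chunking is chosen because both products the iteration needs — Xv and
Xᵀu — stream naturally over row blocks; all accumulation is float64. The
decomposition accepts any object with `shape`/`matvec`/`rmatvec`, so the
chunked path reuses the identical algorithm; equality with the in-memory
result (to ~1e-15 relative on singular values, independent of chunk
size) is a test invariant, not an approximation. The format is
deliberately minimal and language-portable; it does not attempt to match
any existing big-matrix file layout.

## Downstream analysis

Clustering operates on variance-weighted scores U·diag(d), which are
invariant to factor sign flips and weight each axis by the variation it
explains. The algorithm is k-means with `n_init=10` seeded restarts;
the number of clusters maximizes the mean silhouette over the candidate
range, ties toward the smallest k. If all samples coincide in score
space the result is a single cluster with a warning rather than an
error. Embedding is either the first two weighted score columns
(`method="none"`) or a seeded t-SNE; both are deterministic given the
seed.

## The shuffle-decorrelation benchmark

The benchmark emulates scoring feature selection without ground truth in
real data: take a matrix whose columns are genuinely cross-correlated,
choose a random *informative* subset to leave intact, and independently
permute the rows of every other column. Shuffling preserves each
column's value multiset (hence mean and variance exactly) but destroys
its correlation with everything else, driving the mean absolute
between-column correlation to the independence baseline E|r| ≈ √(2/πn).
Selection at sparsity degree k (the union of nonzero loadings across the
K extracted factors, K = 1 by default so the degree is directly
interpretable) is scored against the informative set:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). Degrees 0 and P are
allowed as select-nothing / select-everything endpoints.

The correlated base stands in for the tumor expression matrices such
protocols are usually run on; it is synthetic: X = L·Fᵀ + E with L
(n × r) and F (p × r) standard normal and E unit noise, r = 3 by
default. It reproduces the one property the protocol needs — genuine
cross-feature correlation of roughly uniform strength — but *not* the
heavy tails, block structure, batch effects, or heterogeneous
correlation strengths of real omic data, so benchmark results here
characterize the method's operating curve, not its performance on any
particular real dataset. Replicate r uses seed `base_seed + r`,
recorded in the result table. Default scenario sizes in the test suite
are n = 50, p = 200, 25 replicates at signal fractions 0.1 and 0.8 —
scaled-down study conditions chosen so the full two-scenario benchmark
is a routine desk computation; the replicate count is a config field
and can be raised (e.g. to 1000) for publication-grade curves.

Planted-recovery instances (used for support-recovery and tuning
checks) are rank-1 spikes d₀·u·vᵀ + E with d₀ = 5√n and v supported on
s coordinates with equal magnitudes ±1/√s. Equal magnitudes make exact
support recovery well posed: with, say, Gaussian loadings, a planted
coordinate can carry arbitrarily little signal and no method could
recover the full support reliably.

## Numerical notes and limitations

- Degenerate inputs: all-zero matrices are rejected; a penalty that
  zeroes every loading raises with advice to decrease λ; zero vectors
  pass through the thresholding operators unchanged.
- Singular-value ties make individual singular vectors non-identifiable;
  tests compare subspaces (principal angles) where that matters.
- The alternating iteration solves a non-convex problem; the dense
  initialization makes it deterministic but, like all such schemes, it
  finds a local optimum. In practice the dense start is excellent for
  leading factors.
- Degree tuning refits every candidate, so its cost is linear in the
  grid size; for very large matrices a dense decomposition (λ = 0) or a
  fixed degree is the economical choice.
- Supervised variants (PLS/LDA/reduced-rank regression), per-block
  penalties, and bootstrap inference on the selected supports are out of
  scope.
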