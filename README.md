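# omicsvd

Multi-omic integration and feature selection via elastic-net sparse
singular value decomposition.

## The problem

Modern molecular studies measure each sample on several *omic layers* —
gene expression, DNA methylation, copy number, protein abundance — each a
samples × features matrix with thousands to millions of features. The
shared biology lives in a handful of latent axes of variation that cut
across layers, and the features that actually carry those axes are few.
`omicsvd` is for analysts who want three things at once: integrate the
layers into one factorization, keep only the informative features, and do
it on matrices too large to hold in memory.

## The model

The omic blocks are aligned to a common sample order, mean-imputed,
optionally adjusted for confounders, z-scored per feature, scaled to equal
Frobenius norm per block, and appended column-wise into one *extended
matrix* `X` (n samples × P features). `omicsvd` then computes a sparse SVD

    X  ≈  Σ_k  d_k u_k v_kᵀ,     k = 1 … K

where the sample scores `u_k` are dense unit vectors and the feature
loadings `v_k` are made sparse by the elastic-net proximal operator

    v_i  ←  sign(z_i) · max(|z_i| − αλ, 0) / (1 + (1−α)λ),

with mixing weight α ∈ [0, 1] (α = 1 lasso, α = 0 ridge). Each factor is
fit by alternating iteration from the dense leading singular pair of the
current residual, and factors are extracted sequentially by deflation.
Instead of λ you can request a *degree of sparsity* — the exact number of
nonzero loadings — and λ is derived from the data; the degree itself can
be tuned automatically per factor by minimizing

    BIC(k) = log(RSS_k / nP) + k · log(nP) / nP.

Matrices may live on disk as row-chunked binary files; the whole
decomposition then streams one chunk at a time and returns results
identical to the in-memory path. Downstream helpers cluster the
variance-weighted sample scores (k-means, silhouette-selected k) and embed
them in 2-D. A simulation benchmark scores feature selection by the
shuffle-decorrelation protocol: leave a random subset of features intact,
destroy the cross-sample correlation of all others by per-feature
shuffling, and measure sensitivity/specificity of the selected set.

## Worked example

Two synthetic layers share one sparse latent factor: 8 of 40 expression
features and 5 of 30 methylation features separate two patient groups.

```python
import numpy as np
from omicsvd import OmicBlock, build_extended_matrix, decompose, cluster_scores

rng = np.random.default_rng(0)
samples = [f"patient{i:02d}" for i in range(60)]
group = np.repeat([1.0, -1.0], 30)
expr = rng.standard_normal((60, 40));      expr[:, :8] += 2.0 * group[:, None]
meth = 5.0 * rng.standard_normal((60, 30)); meth[:, :5] += 6.0 * group[:, None]

blocks = [
    OmicBlock(expr, samples, [f"gene{j}" for j in range(40)], "expr"),
    OmicBlock(meth, samples, [f"cpg{j}" for j in range(30)], "meth"),
]
X = build_extended_matrix(blocks)
factors, tuning = decompose(X, K=2, penalty="auto")
print("singular values:", np.round(factors.d, 4))
print("tuned degrees:  ", tuning.selected_degree)
clusters = cluster_scores(factors.U, factors.d, range(2, 6), seed=0)
print("chosen k:", clusters.chosen_k)
```

prints

```
singular values: [0.5094 0.2502]
tuned degrees:   [15  5]
chosen k: 2
```

The first factor's 15 nonzero loadings contain all 13 planted features
(the 8 genes and 5 CpGs) plus two spurious ones — the default tuning grid
is log-spaced, and 15 is the candidate nearest the planted 13 — and
clustering the scores recovers the two patient groups exactly. Note the
methylation block entered at 5–6× the expression scale; block
normalization makes that irrelevant.

The same pipeline is available from the shell:

```sh
omicsvd decompose --block expr=expr.tsv --block meth=meth.tsv \
    -k 2 --auto --cluster --out-dir results/
omicsvd simulate --signal-fraction 0.1 --replicates 25 --out bench.tsv
```

`decompose` writes `U.tsv`, `V.tsv`, `d.tsv` (plus the dense solution,
the tuning grid, cluster labels, and a `manifest.json` with checksums);
`simulate` writes a tidy per-replicate table of confusion counts and
sensitivity/specificity.

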