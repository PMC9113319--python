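"""Cluster analysis and low-dimensional embedding of latent sample scores.

Samples are represented by their variance-weighted scores ``U diag(d)`` —
each latent axis contributes in proportion to the variation it explains, and
the representation is invariant to the sign ambiguity of singular vectors.
Clustering is k-means with multiple seeded restarts; the number of clusters
is chosen by mean silhouette over a candidate range (ties toward the
smallest k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

__all__ = ["ClusterResult", "cluster_scores", "embed_scores"]


@dataclass
class ClusterResult:
    """Per-sample cluster labels (1-based) plus the silhouette model-selection trace."""

    labels: NDArray[np.int_]
    k: int
    quality: dict[int, float]
    chosen_k: int
    sample_ids: list[str] | None = None

    def write_tsv(self, path: str | Path) -> None:
        rows = self.sample_ids or [f"sample{i + 1}" for i in range(self.labels.size)]
        pd.DataFrame({"cluster": self.labels}, index=rows).to_csv(
            path, sep="\t", index_label="sample_id"
        )


def _weighted_scores(U: NDArray, d: NDArray) -> NDArray[np.float64]:
    U = np.asarray(U, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64).ravel()
    if U.ndim != 2 or U.shape[1] != d.size:
        raise ValueError(f"U has {U.shape[1] if U.ndim == 2 else '?'} columns for {d.size} singular values")
    return U * d


def cluster_scores(
    U: NDArray,
    d: NDArray,
    k_range=range(2, 9),
    seed: int = 0,
    n_init: int = 10,
    sample_ids: list[str] | None = None,
) -> ClusterResult:
    """k-means on variance-weighted scores with silhouette model selection.

    Degenerate input (all samples identical in score space) is reported as a
    single cluster with a warning rather than an error.
    """
    S = _weighted_scores(U, d)
    n = S.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if np.allclose(S, S[0], atol=1e-12):
        warnings.warn("all samples identical in score space; reporting one cluster", stacklevel=2)
        return ClusterResult(
            labels=np.ones(n, dtype=int), k=1, quality={}, chosen_k=1, sample_ids=sample_ids
        )
    quality: dict[int, float] = {}
    labels_by_k: dict[int, NDArray[np.int_]] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(S)
        if len(np.unique(lab)) < 2:
            quality[k] = -1.0
        else:
            quality[k] = float(silhouette_score(S, lab))
        labels_by_k[k] = lab
    best = max(quality.values())
    chosen_k = min(k for k, q in quality.items() if q == best)  # parsimony on ties
    return ClusterResult(
        labels=labels_by_k[chosen_k] + 1,
        k=chosen_k,
        quality=quality,
        chosen_k=chosen_k,
        sample_ids=sample_ids,
    )


def embed_scores(
    U: NDArray, d: NDArray, method: str = "none", seed: int = 0
) -> NDArray[np.float64]:
    """2-D coordinates of the samples for plotting.

    ``method="none"`` returns the first two variance-weighted score columns
    (zero-padded if only one factor is available); ``method="tsne"`` runs a
    seeded t-SNE on the full weighted scores.
    """
    S = _weighted_scores(U, d)
    n = S.shape[0]
    if n < 5:
        raise ValueError(f"embedding requires at least 5 samples, got {n}")
    if method == "none":
        if S.shape[1] >= 2:
            return S[:, :2].copy()
        return np.column_stack([S[:, 0], np.zeros(n)])
    if method == "tsne":
        perplexity = min(30.0, (n - 1) / 3.0)
        ts = TSNE(
            n_components=2, random_state=seed, init="pca", perplexity=perplexity
        )
        return np.asarray(ts.fit_transform(S), dtype=np.float64)
    raise ValueError(f"unknown embedding method {method!r}; use 'none' or 'tsne'")


def plot_scores(
    coords: NDArray, labels: NDArray | None, path: str | Path, title: str = "Latent scores"
) -> None:
    """Scatter plot of 2-D coordinates colored by cluster label (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(5, 4))
    c = None if labels is None else np.asarray(labels)
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=c, cmap="tab10", s=18)
    if labels is not None:
        fig.colorbar(sc, ax=ax, label="cluster")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
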