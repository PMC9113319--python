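"""Shuffle-decorrelation benchmark for feature-selection performance.

The benchmark emulates the standard protocol for scoring omic
feature-selection methods without knowing ground truth in real data: start
from a matrix whose columns carry genuine cross-feature correlation, pick a
random subset of *informative* features to leave intact, and destroy the
signal in every other feature by independently permuting its values across
samples. A method is then scored by how well the features it selects match
the intact set — sensitivity (informative features selected) and specificity
(decorrelated features rejected) — across a grid of sparsity degrees and
many replicates.

Because the protocol only needs a correlated base matrix, the generator here
plants a low-rank Gaussian factor structure (``X = L F^T + E``) in place of
the tumor expression profiles typically used, keeping the shuffle protocol
itself identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .core import PenaltySpec
from .preprocess import OmicBlock, standardize_and_normalize
from .ssvd import decompose

__all__ = [
    "BenchmarkConfig",
    "BenchmarkResult",
    "make_correlated_base",
    "shuffle_decorrelate",
    "confusion_stats",
    "run_benchmark",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study design for one benchmark scenario.

    ``signal_fraction`` is the proportion of features left intact (the
    informative set); ``degree_grid`` the sparsity degrees at which selection
    is scored (0 and p are allowed as select-nothing / select-everything
    endpoints); ``alpha`` the elastic-net mixing weight; ``n_factors`` the
    number of latent factors whose nonzero loadings are pooled into the
    selected set.
    """

    signal_fraction: float
    n_replicates: int
    degree_grid: tuple[int, ...]
    alpha: float = 1.0
    seed: int = 0
    n_factors: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.signal_fraction < 1.0:
            raise ValueError(f"signal_fraction must lie in (0, 1), got {self.signal_fraction}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.degree_grid:
            raise ValueError("degree_grid is empty")
        if any(k < 0 for k in self.degree_grid):
            raise ValueError("degrees must be nonnegative")


@dataclass
class BenchmarkResult:
    """Per-replicate confusion counts plus aggregated operating curves."""

    table: pd.DataFrame  # replicate, seed, degree, TP, FP, TN, FN, sensitivity, specificity
    informative_sets: list[NDArray[np.int_]]
    config: BenchmarkConfig

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation of sensitivity/specificity per degree."""
        return (
            self.table.groupby("degree")[["sensitivity", "specificity"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot_curves(self, path: str | Path) -> None:
        """Sensitivity/specificity vs. degree with inter-replicate bands."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        agg = self.table.groupby("degree")[["sensitivity", "specificity"]].agg(["mean", "std"])
        degrees = agg.index.to_numpy()
        fig, ax = plt.subplots(figsize=(5.5, 4))
        for stat, color in (("sensitivity", "C0"), ("specificity", "C1")):
            m = agg[(stat, "mean")].to_numpy()
            s = np.nan_to_num(agg[(stat, "std")].to_numpy())
            ax.plot(degrees, m, marker="o", color=color, label=stat)
            ax.fill_between(degrees, m - s, m + s, color=color, alpha=0.2)
        ax.set_xlabel("sparsity degree (nonzero loadings)")
        ax.set_ylabel("rate")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        ax.set_title(
            f"signal fraction {self.config.signal_fraction:g}, "
            f"{self.config.n_replicates} replicates"
        )
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def make_correlated_base(
    n: int, p: int, latent_rank: int, seed: int
) -> NDArray[np.float64]:
    """Gaussian matrix with planted low-rank structure: ``X = L F^T + E``.

    ``L`` (n x r) and ``F`` (p x r) are standard normal, ``E`` unit noise, so
    columns carry genuine cross-correlation whenever ``latent_rank > 0``;
    ``latent_rank=0`` gives pure independent noise.
    """
    if latent_rank >= min(n, p):
        raise ValueError(f"latent_rank must be < min(n, p) = {min(n, p)}")
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n, p))
    if latent_rank == 0:
        return E
    L = rng.standard_normal((n, latent_rank))
    F = rng.standard_normal((p, latent_rank))
    return L @ F.T + E


def planted_rank1(
    n: int,
    p: int,
    support_size: int,
    d0: float,
    seed: int,
) -> tuple[NDArray[np.float64], NDArray[np.int_]]:
    """Rank-1 spike with a sparse loading vector in unit Gaussian noise.

    ``X = d0 u v^T + E`` with ``u`` a random unit vector and ``v`` supported
    on ``support_size`` random coordinates with equal-magnitude entries
    ``±1/sqrt(support_size)`` (random signs), so every planted loading
    carries the same signal and support recovery is well posed. Returns the
    matrix and the sorted planted support.
    """
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    u /= np.linalg.norm(u)
    support = np.sort(rng.choice(p, size=support_size, replace=False))
    v = np.zeros(p)
    v[support] = rng.choice([-1.0, 1.0], size=support_size) / np.sqrt(support_size)
    return d0 * np.outer(u, v) + rng.standard_normal((n, p)), support


def shuffle_decorrelate(
    X: NDArray[np.float64], informative, seed: int
) -> NDArray[np.float64]:
    """Independently permute the rows of every non-informative column.

    Columns in ``informative`` are returned untouched, conserving their
    natural correlation; every other column becomes a random permutation of
    its own values (same multiset, hence identical mean and variance), which
    destroys its correlation with everything else.
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    informative = np.asarray(sorted(set(int(j) for j in np.asarray(informative).ravel())), dtype=int)
    if informative.size and (informative[0] < 0 or informative[-1] >= p):
        raise IndexError(f"informative indices must lie in [0, {p - 1}]")
    keep = np.zeros(p, dtype=bool)
    keep[informative] = True
    rng = np.random.default_rng(seed)
    out = X.copy()
    for j in range(p):
        if not keep[j]:
            out[:, j] = X[rng.permutation(n), j]
    return out


def confusion_stats(selected, informative, p: int) -> tuple[float, float]:
    """Sensitivity and specificity of a selected feature set.

    sensitivity = |selected ∩ informative| / |informative|;
    specificity = |rejected ∩ non-informative| / |non-informative|.
    """
    selected = {int(j) for j in selected}
    informative = {int(j) for j in informative}
    if not informative:
        raise ValueError("informative set is empty; sensitivity is undefined")
    bad = (selected | informative) - set(range(p))
    if bad:
        raise IndexError(f"indices out of range [0, {p - 1}]: {sorted(bad)[:5]}")
    tp = len(selected & informative)
    tn = p - len(selected | informative)
    return tp / len(informative), tn / (p - len(informative))


def _selected_features(X: NDArray[np.float64], degree: int, alpha: float, n_factors: int) -> set[int]:
    p = X.shape[1]
    if degree == 0:
        return set()
    if degree >= p:
        return set(range(p))
    factors, _ = decompose(
        X, K=n_factors, penalty=PenaltySpec(alpha=alpha, degree=degree)
    )
    return set(np.flatnonzero(np.any(factors.V != 0.0, axis=1)).tolist())


def run_benchmark(
    config: BenchmarkConfig,
    base: NDArray[np.float64] | None = None,
    n: int = 50,
    p: int = 200,
    latent_rank: int = 3,
) -> BenchmarkResult:
    """Run the shuffle-decorrelation benchmark for one scenario.

    Per replicate: draw an informative set of ``round(signal_fraction * p)``
    features, shuffle-decorrelate the rest of the base matrix, standardize,
    decompose at every degree in the grid, pool nonzero loadings across
    factors into the selected set, and tally confusion counts against the
    informative set. Replicate r uses seed ``config.seed + r`` (recorded in
    the result table).
    """
    if base is None:
        base = make_correlated_base(n, p, latent_rank, config.seed)
    base = np.asarray(base, dtype=np.float64)
    n, p = base.shape
    if max(config.degree_grid) > p:
        raise ValueError(f"degree grid exceeds the number of features ({p})")
    n_signal = int(round(config.signal_fraction * p))
    if n_signal < 1 or n_signal >= p:
        raise ValueError("signal_fraction leaves no informative or no null features")
    rows = []
    informative_sets = []
    for rep in range(config.n_replicates):
        rep_seed = config.seed + rep
        rng = np.random.default_rng(rep_seed)
        informative = np.sort(rng.choice(p, size=n_signal, replace=False))
        informative_sets.append(informative)
        shuffled = shuffle_decorrelate(base, informative, seed=rep_seed)
        block = OmicBlock(
            values=shuffled,
            sample_ids=[f"s{i}" for i in range(n)],
            feature_ids=[f"f{j}" for j in range(p)],
            block_label="sim",
        )
        X = standardize_and_normalize([block]).values
        inf_set = set(informative.tolist())
        for degree in config.degree_grid:
            selected = _selected_features(X, int(degree), config.alpha, config.n_factors)
            tp = len(selected & inf_set)
            fp = len(selected - inf_set)
            fn = n_signal - tp
            tn = p - n_signal - fp
            rows.append(
                {
                    "replicate": rep,
                    "seed": rep_seed,
                    "degree": int(degree),
                    "TP": tp,
                    "FP": fp,
                    "TN": tn,
                    "FN": fn,
                    "sensitivity": tp / n_signal,
                    "specificity": tn / (p - n_signal),
                }
            )
    return BenchmarkResult(
        table=pd.DataFrame(rows), informative_sets=informative_sets, config=config
    )
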