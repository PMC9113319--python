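"""Turn a list of omic blocks into one clean, standardized extended matrix.

An *omic block* is one samples x features numeric matrix from a single data
layer (expression, methylation, copy number, ...). Integration proceeds by

1. aligning all blocks to a common sample order,
2. mean-imputing missing entries per feature,
3. optionally residualizing every feature on a covariate design
   (confounder adjustment),
4. z-scoring each feature and dividing each block by its Frobenius norm so
   every block contributes equal total variance,
5. concatenating the blocks column-wise into the *extended matrix* that the
   sparse SVD factorizes.

Blocks are read from TSV/CSV (header row of feature IDs, first column of
sample IDs, ``NA``/empty = missing) or MatrixMarket ``.mtx`` files with
sidecar row/column ID lists.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from numpy.typing import NDArray


class AlignmentError(ValueError):
    """Sample IDs do not match across blocks."""


@dataclass
class OmicBlock:
    """One samples x features numeric matrix with identifiers.

    ``values`` stores missing entries as NaN; ``missing_mask`` records where
    they were (and is retained after imputation for provenance).
    """

    values: NDArray[np.float64]
    sample_ids: list[str]
    feature_ids: list[str]
    block_label: str = "block"
    missing_mask: NDArray[np.bool_] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("block values must be 2-D (samples x features)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample IDs for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature IDs for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample IDs in block {self.block_label!r}")
        if len(set(self.feature_ids)) != p:
            raise ValueError(f"duplicate feature IDs in block {self.block_label!r}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, block_label: str = "block") -> "OmicBlock":
        return cls(
            values=df.to_numpy(dtype=np.float64),
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            block_label=block_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class CovariateTable:
    """Numeric covariate design, same sample order as the blocks.

    Categorical covariates are expanded to treatment-coded indicators (first
    level dropped). Missing covariate values are an error — silently imputing
    a confounder would distort the adjustment.
    """

    values: NDArray[np.float64]
    covariate_names: list[str]
    sample_ids: list[str] | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovariateTable":
        if df.isna().to_numpy().any():
            raise ValueError("covariates contain missing values; impute or drop them first")
        expanded = pd.get_dummies(df, drop_first=True, dtype=np.float64)
        return cls(
            values=expanded.to_numpy(dtype=np.float64),
            covariate_names=[str(c) for c in expanded.columns],
            sample_ids=[str(s) for s in df.index],
        )


@dataclass
class ExtendedMatrix:
    """Column-wise concatenation of preprocessed blocks.

    ``column_map`` traces every column back to its ``(block_label,
    feature_id)``; the stored per-column means/scales and per-block norms
    allow an exact inverse transform.
    """

    values: NDArray[np.float64]
    sample_ids: list[str]
    column_map: list[tuple[str, str]]
    means: NDArray[np.float64]
    scales: NDArray[np.float64]
    block_norms: dict[str, float]
    block_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def inverse_transform(self) -> NDArray[np.float64]:
        """Undo normalization and standardization (returns the imputed matrix)."""
        out = self.values.copy()
        for label, sl in self.block_slices.items():
            out[:, sl] *= self.block_norms[label]
        return out * self.scales + self.means

    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV plus a JSON sidecar with the provenance maps."""
        path = Path(path)
        cols = [f"{b}::{f}" for b, f in self.column_map]
        pd.DataFrame(self.values, index=self.sample_ids, columns=cols).to_csv(
            path, sep="\t", index_label="sample_id"
        )
        sidecar = {
            "column_map": [list(c) for c in self.column_map],
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "block_norms": self.block_norms,
            "block_slices": {k: [v.start, v.stop] for k, v in self.block_slices.items()},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


# ---------------------------------------------------------------------------
# readers


def read_block(path: str | Path, block_label: str | None = None) -> OmicBlock:
    """Read an omic block from TSV/CSV or MatrixMarket.

    Delimited text: first row = feature IDs, first column = sample IDs,
    ``NA`` or empty cell = missing. MatrixMarket: ``<stem>.mtx`` with sidecar
    ``<stem>.rows.txt`` / ``<stem>.cols.txt`` ID lists (one per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"block file not found: {path}")
    label = block_label or path.stem
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = path.with_suffix(".rows.txt").read_text().split()
        cols = path.with_suffix(".cols.txt").read_text().split()
        return OmicBlock(np.asarray(mat, dtype=np.float64), rows, cols, label)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    return OmicBlock.from_dataframe(df, label)


def read_covariates(path: str | Path) -> CovariateTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariate file not found: {path}")
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    return CovariateTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# pipeline operations


def align_blocks(blocks: list[OmicBlock]) -> list[OmicBlock]:
    """Reorder all blocks to the sample order of the first block.

    Raises :class:`AlignmentError` listing the symmetric difference when the
    blocks do not share the same set of sample IDs.
    """
    if not blocks:
        raise ValueError("need at least one block")
    ref = blocks[0].sample_ids
    ref_set = set(ref)
    out = [blocks[0]]
    for blk in blocks[1:]:
        if set(blk.sample_ids) != ref_set:
            diff = sorted(ref_set.symmetric_difference(blk.sample_ids))
            raise AlignmentError(
                f"sample IDs of block {blk.block_label!r} do not match block "
                f"{blocks[0].block_label!r}; symmetric difference: {diff}"
            )
        pos = {s: i for i, s in enumerate(blk.sample_ids)}
        perm = np.array([pos[s] for s in ref])
        out.append(
            OmicBlock(
                values=blk.values[perm],
                sample_ids=list(ref),
                feature_ids=blk.feature_ids,
                block_label=blk.block_label,
                missing_mask=blk.missing_mask[perm],
            )
        )
    return out


def impute_means(block: OmicBlock) -> OmicBlock:
    """Replace each missing entry by its feature's mean over observed samples."""
    mask = block.missing_mask
    if not mask.any():
        return block
    fully_missing = mask.all(axis=0)
    if fully_missing.any():
        bad = [block.feature_ids[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(
            f"features entirely missing in block {block.block_label!r}: {bad}"
        )
    values = block.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(np.where(mask, np.nan, values), axis=0)
    rows, cols = np.nonzero(mask)
    values[rows, cols] = col_means[cols]
    return OmicBlock(
        values=values,
        sample_ids=block.sample_ids,
        feature_ids=block.feature_ids,
        block_label=block.block_label,
        missing_mask=mask,
    )


def adjust_covariates(
    block_values: NDArray[np.float64], covariates: CovariateTable
) -> NDArray[np.float64]:
    """Residualize every feature on the covariate design (with intercept).

    Returns the least-squares residuals, which are exactly orthogonal to the
    intercept and to every covariate column. Raises on a rank-deficient
    design (collinear covariates).
    """
    X = np.asarray(block_values, dtype=np.float64)
    n = X.shape[0]
    if covariates.values.shape[0] != n:
        raise ValueError(
            f"covariate rows ({covariates.values.shape[0]}) != samples ({n})"
        )
    design = np.column_stack([np.ones(n), covariates.values])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "covariate design is rank deficient (intercept + "
            f"{covariates.covariate_names}); remove collinear covariates"
        )
    q, _ = np.linalg.qr(design)
    return X - q @ (q.T @ X)


def standardize_and_normalize(blocks: list[OmicBlock]) -> ExtendedMatrix:
    """z-score each feature, equalize block norms, concatenate column-wise.

    Each column is centered to mean 0 and scaled to sample standard deviation
    1 (divisor ``n-1``); constant features are set to all zeros (flagged with
    a warning, not dropped, so the column map stays aligned). Each
    standardized block is then divided by its Frobenius norm so every block
    contributes equal total variance to the extended matrix.
    """
    if not blocks:
        raise ValueError("need at least one block")
    ref = blocks[0].sample_ids
    for blk in blocks[1:]:
        if blk.sample_ids != ref:
            raise AlignmentError("blocks are not aligned; call align_blocks first")
    parts, column_map, means, scales, block_norms, block_slices = [], [], [], [], {}, {}
    start = 0
    for blk in blocks:
        if np.isnan(blk.values).any():
            raise ValueError(
                f"block {blk.block_label!r} has missing values; call impute_means first"
            )
        if blk.block_label in block_norms:
            raise ValueError(f"duplicate block label {blk.block_label!r}")
        mu = blk.values.mean(axis=0)
        sd = blk.values.std(axis=0, ddof=1) if blk.shape[0] > 1 else np.zeros(blk.shape[1])
        constant = sd == 0
        if constant.any():
            names = [blk.feature_ids[j] for j in np.flatnonzero(constant)[:10]]
            warnings.warn(
                f"{int(constant.sum())} constant feature(s) in block "
                f"{blk.block_label!r} set to zero (e.g. {names})",
                stacklevel=2,
            )
        safe_sd = np.where(constant, 1.0, sd)
        z = (blk.values - mu) / safe_sd
        z[:, constant] = 0.0
        norm = float(np.linalg.norm(z))
        if norm == 0:
            norm = 1.0
        parts.append(z / norm)
        column_map.extend((blk.block_label, f) for f in blk.feature_ids)
        means.append(mu)
        scales.append(np.where(constant, 0.0, sd))
        block_norms[blk.block_label] = norm
        block_slices[blk.block_label] = slice(start, start + blk.shape[1])
        start += blk.shape[1]
    return ExtendedMatrix(
        values=np.hstack(parts),
        sample_ids=list(ref),
        column_map=column_map,
        means=np.concatenate(means),
        scales=np.concatenate(scales),
        block_norms=block_norms,
        block_slices=block_slices,
    )


def build_extended_matrix(
    blocks: list[OmicBlock], covariates: CovariateTable | None = None
) -> ExtendedMatrix:
    """Full pipeline: align -> impute -> adjust covariates -> standardize."""
    blocks = align_blocks(blocks)
    blocks = [impute_means(b) for b in blocks]
    if covariates is not None and covariates.sample_ids is not None:
        ref = blocks[0].sample_ids
        if covariates.sample_ids != ref:
            if set(covariates.sample_ids) != set(ref):
                diff = sorted(set(ref).symmetric_difference(covariates.sample_ids))
                raise AlignmentError(
                    f"covariate sample IDs do not match blocks; symmetric difference: {diff}"
                )
            pos = {s: i for i, s in enumerate(covariates.sample_ids)}
            perm = np.array([pos[s] for s in ref])
            covariates = CovariateTable(
                values=covariates.values[perm],
                covariate_names=covariates.covariate_names,
                sample_ids=list(ref),
            )
    if covariates is not None:
        blocks = [
            OmicBlock(
                values=adjust_covariates(b.values, covariates),
                sample_ids=b.sample_ids,
                feature_ids=b.feature_ids,
                block_label=b.block_label,
                missing_mask=b.missing_mask,
            )
            for b in blocks
        ]
    return standardize_and_normalize(blocks)
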