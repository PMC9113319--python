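"""File-backed chunked matrices for out-of-core decomposition.

A :class:`ChunkedMatrix` stores an n x P float64 matrix on disk as a flat
row-major binary file with a JSON header sidecar (shape, dtype, chunk size,
optional column provenance). All linear algebra the sparse SVD needs —
``matvec`` (``X v``), ``rmatvec`` (``X^T u``) and the squared Frobenius norm
— streams over row chunks, so peak resident data is one chunk plus the
result regardless of matrix size. Reassembling the chunks reproduces the
logical matrix bit-for-bit, and every operation is independent of the chunk
size by construction (all accumulation in float64).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from numpy.typing import NDArray

from .preprocess import ExtendedMatrix

__all__ = ["ChunkedMatrix", "to_chunked", "open_chunked", "chunked_matvec", "chunked_rmatvec"]

_MAGIC = "omicsvd-chunked-v1"


@dataclass
class ChunkedMatrix:
    """On-disk row-chunked matrix: ``<path>.bin`` values + ``<path>.json`` header."""

    path: Path
    shape: tuple[int, int]
    chunk_rows: int
    dtype: str = "float64"
    column_map: list[tuple[str, str]] | None = None
    sample_ids: list[str] | None = None

    @property
    def bin_path(self) -> Path:
        return self.path.with_suffix(".bin")

    @property
    def header_path(self) -> Path:
        return self.path.with_suffix(".json")

    @property
    def n_chunks(self) -> int:
        n = self.shape[0]
        return (n + self.chunk_rows - 1) // self.chunk_rows

    def iter_chunks(self) -> Iterator[tuple[int, int, NDArray[np.float64]]]:
        """Yield ``(row_start, row_stop, values)`` one chunk at a time."""
        n, p = self.shape
        itemsize = np.dtype(self.dtype).itemsize
        with open(self.bin_path, "rb") as fh:
            for start in range(0, n, self.chunk_rows):
                stop = min(start + self.chunk_rows, n)
                fh.seek(start * p * itemsize)
                buf = np.fromfile(fh, dtype=self.dtype, count=(stop - start) * p)
                yield start, stop, buf.reshape(stop - start, p).astype(np.float64, copy=False)

    # matrix-free contract used by the decomposition ------------------------

    def matvec(self, v: NDArray) -> NDArray[np.float64]:
        v = np.asarray(v, dtype=np.float64).ravel()
        n, p = self.shape
        if v.shape != (p,):
            raise ValueError(f"matvec expects a length-{p} vector, got shape {v.shape}")
        out = np.empty(n, dtype=np.float64)
        for start, stop, chunk in self.iter_chunks():
            out[start:stop] = chunk @ v
        return out

    def rmatvec(self, u: NDArray) -> NDArray[np.float64]:
        u = np.asarray(u, dtype=np.float64).ravel()
        n, p = self.shape
        if u.shape != (n,):
            raise ValueError(f"rmatvec expects a length-{n} vector, got shape {u.shape}")
        out = np.zeros(p, dtype=np.float64)
        for start, stop, chunk in self.iter_chunks():
            out += chunk.T @ u[start:stop]
        return out

    def frob2(self) -> float:
        total = 0.0
        for _, _, chunk in self.iter_chunks():
            total += float(np.sum(chunk * chunk))
        return total

    def to_array(self) -> NDArray[np.float64]:
        """Read the whole matrix back into memory (tests / small inputs)."""
        out = np.empty(self.shape, dtype=np.float64)
        for start, stop, chunk in self.iter_chunks():
            out[start:stop] = chunk
        return out


def to_chunked(
    X: ExtendedMatrix | NDArray[np.float64],
    chunk_rows: int,
    path: str | Path,
) -> ChunkedMatrix:
    """Write X to disk as a chunked matrix; read-back equals X bit-for-bit."""
    if chunk_rows < 1:
        raise ValueError(f"chunk_rows must be >= 1, got {chunk_rows}")
    column_map = sample_ids = None
    if isinstance(X, ExtendedMatrix):
        column_map, sample_ids = list(X.column_map), list(X.sample_ids)
        X = X.values
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    path = Path(path)
    cm = ChunkedMatrix(
        path=path,
        shape=X.shape,
        chunk_rows=int(chunk_rows),
        column_map=column_map,
        sample_ids=sample_ids,
    )
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(cm.bin_path, "wb") as fh:
            for start in range(0, X.shape[0], cm.chunk_rows):
                X[start : start + cm.chunk_rows].tofile(fh)
        header = {
            "format": _MAGIC,
            "shape": list(X.shape),
            "dtype": cm.dtype,
            "chunk_rows": cm.chunk_rows,
            "column_map": [list(c) for c in column_map] if column_map else None,
            "sample_ids": sample_ids,
        }
        cm.header_path.write_text(json.dumps(header))
    except OSError as exc:
        raise OSError(f"failed to write chunked matrix at {path}: {exc}") from exc
    return cm


def open_chunked(path: str | Path) -> ChunkedMatrix:
    """Open an existing chunked matrix from its header path."""
    path = Path(path)
    header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise FileNotFoundError(f"chunked matrix header not found: {header_path}")
    header = json.loads(header_path.read_text())
    if header.get("format") != _MAGIC:
        raise ValueError(f"{header_path} is not a chunked-matrix header")
    return ChunkedMatrix(
        path=path,
        shape=tuple(header["shape"]),
        chunk_rows=int(header["chunk_rows"]),
        dtype=header["dtype"],
        column_map=[tuple(c) for c in header["column_map"]]
        if header.get("column_map")
        else None,
        sample_ids=header.get("sample_ids"),
    )


def chunked_matvec(A: ChunkedMatrix, v: NDArray) -> NDArray[np.float64]:
    """Streaming product ``A v`` (one chunk resident at a time)."""
    return A.matvec(v)


def chunked_rmatvec(A: ChunkedMatrix, u: NDArray) -> NDArray[np.float64]:
    """Streaming product ``A^T u`` (one chunk resident at a time)."""
    return A.rmatvec(u)
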