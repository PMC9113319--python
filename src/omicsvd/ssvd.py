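"""Sparse singular value decomposition with elastic-net penalized loadings.

The factorization ``X ~ sum_k d_k u_k v_k^T`` is extracted one factor at a
time. Each rank-1 factor is fit by alternating iteration: starting from the
leading dense singular pair of the current residual, repeat

    w <- X^T u;  v <- EN-threshold(w);  v <- v / ||v||;  u <- X v / ||X v||

until the relative change in ``v`` falls below ``tol``; then ``d = u^T X v``
and the residual is deflated by ``d u v^T``. Sparsity is imposed on the
feature-side (right) singular vectors only; sample scores stay dense.

The number of nonzero loadings per factor (the *degree of sparsity*) can be
fixed, or tuned automatically by minimizing a BIC over a candidate grid:

    BIC(k) = log(RSS_k / (n P)) + k * log(n P) / (n P),

where ``RSS_k`` is the squared Frobenius norm of the rank-1 residual at
degree ``k``. Matrices may be in-memory arrays, preprocessed
:class:`~omicsvd.preprocess.ExtendedMatrix` objects, or any chunked/on-disk
object exposing ``shape``, ``matvec`` and ``rmatvec`` (see
:mod:`omicsvd.outofcore`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla
from numpy.typing import NDArray

from .core import PenaltySpec, degree_lambda, en_threshold, threshold_to_degree
from .preprocess import ExtendedMatrix

__all__ = [
    "SvdFactors",
    "TuningResult",
    "dense_svd",
    "rank1_ssvd",
    "deflate",
    "tune_degree",
    "decompose",
]

# fixed ARPACK starting vector seed: decompositions are deterministic and
# backend-independent by construction, not by user-supplied seeding
_INIT_SEED = 987654321


class ConvergenceWarning(UserWarning):
    pass


class FlatTuningCurveWarning(UserWarning):
    """The tuning criterion has no minimum materially below the dense fit."""


@dataclass
class SvdFactors:
    """Rank-K decomposition: sample scores, singular values, feature loadings.

    ``U`` is n x K (dense unit columns), ``d`` length-K descending, ``V`` is
    P x K (unit columns, sparse when penalized). ``nnz`` counts nonzero
    loadings per factor. Sign convention: the largest-magnitude loading of
    each factor is positive.
    """

    U: NDArray[np.float64]
    d: NDArray[np.float64]
    V: NDArray[np.float64]
    nnz: NDArray[np.int_]
    penalty: PenaltySpec | None = None
    converged: NDArray[np.bool_] | None = None
    n_iter: NDArray[np.int_] | None = None
    dense: "SvdFactors | None" = None
    sample_ids: list[str] | None = None
    column_map: list[tuple[str, str]] | None = None

    @property
    def K(self) -> int:
        return self.d.size

    def write_tsv(self, outdir: str | Path, prefix: str = "") -> None:
        """Write U / V / summary (d, nnz, convergence) as TSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        k_names = [f"factor{k + 1}" for k in range(self.K)]
        rows = self.sample_ids or [f"sample{i + 1}" for i in range(self.U.shape[0])]
        pd.DataFrame(self.U, index=rows, columns=k_names).to_csv(
            outdir / f"{prefix}U.tsv", sep="\t", index_label="sample_id"
        )
        if self.column_map is not None:
            vidx = pd.MultiIndex.from_tuples(self.column_map, names=["block", "feature"])
        else:
            vidx = pd.Index(
                [f"feature{j + 1}" for j in range(self.V.shape[0])], name="feature"
            )
        pd.DataFrame(self.V, index=vidx, columns=k_names).to_csv(
            outdir / f"{prefix}V.tsv", sep="\t"
        )
        summary = pd.DataFrame(
            {
                "d": self.d,
                "nnz": self.nnz,
                "converged": self.converged
                if self.converged is not None
                else np.ones(self.K, dtype=bool),
                "n_iter": self.n_iter if self.n_iter is not None else np.zeros(self.K, int),
            },
            index=pd.Index(k_names, name="factor"),
        )
        summary.to_csv(outdir / f"{prefix}d.tsv", sep="\t")


@dataclass
class TuningResult:
    """Grid of candidate sparsity degrees vs. criterion values per factor."""

    candidate_degrees: NDArray[np.int_]
    criterion_values: NDArray[np.float64]  # n_factors x n_candidates
    selected_degree: NDArray[np.int_]
    criterion_name: str = "rank1_bic"

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.criterion_values,
            index=pd.Index(
                [f"factor{k + 1}" for k in range(self.criterion_values.shape[0])],
                name="factor",
            ),
            columns=[str(k) for k in self.candidate_degrees],
        )
        df["selected_degree"] = self.selected_degree
        df.to_csv(path, sep="\t")


@dataclass
class Rank1Result:
    u: NDArray[np.float64]
    d: float
    v: NDArray[np.float64]
    converged: bool = True
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list)

    def __iter__(self):
        return iter((self.u, self.d, self.v))


# ---------------------------------------------------------------------------
# residual workspaces: in-memory (explicit deflation) and matrix-free


class _DenseWork:
    def __init__(self, X: NDArray[np.float64]):
        self.R = np.array(X, dtype=np.float64, copy=True)
        self.shape = self.R.shape

    def matvec(self, v):
        return self.R @ v

    def rmatvec(self, u):
        return self.R.T @ u

    def frob2(self) -> float:
        return float(np.sum(self.R * self.R))

    def deflate(self, u, d, v) -> None:
        self.R -= d * np.outer(u, v)

    def is_zero(self) -> bool:
        return not self.R.any()


class _OpWork:
    """Matrix-free residual: base operator minus accumulated rank-1 factors."""

    def __init__(self, base):
        self.base = base
        self.shape = tuple(base.shape)
        self.us: list[NDArray[np.float64]] = []
        self.ds: list[float] = []
        self.vs: list[NDArray[np.float64]] = []

    def matvec(self, v):
        v = np.asarray(v, dtype=np.float64).ravel()
        out = np.asarray(self.base.matvec(v), dtype=np.float64).ravel()
        for u_j, d_j, v_j in zip(self.us, self.ds, self.vs):
            out -= d_j * (v_j @ v) * u_j
        return out

    def rmatvec(self, u):
        u = np.asarray(u, dtype=np.float64).ravel()
        out = np.asarray(self.base.rmatvec(u), dtype=np.float64).ravel()
        for u_j, d_j, v_j in zip(self.us, self.ds, self.vs):
            out -= d_j * (u_j @ u) * v_j
        return out

    def frob2(self) -> float:
        total = float(self.base.frob2())
        for u_j, d_j, v_j in zip(self.us, self.ds, self.vs):
            total -= 2.0 * d_j * float(u_j @ self.base.matvec(v_j))
        for j, (u_j, d_j, v_j) in enumerate(zip(self.us, self.ds, self.vs)):
            for u_k, d_k, v_k in zip(self.us, self.ds, self.vs):
                total += d_j * d_k * float(u_j @ u_k) * float(v_j @ v_k)
        return total

    def deflate(self, u, d, v) -> None:
        self.us.append(u.copy())
        self.ds.append(float(d))
        self.vs.append(v.copy())

    def is_zero(self) -> bool:
        return False  # checked lazily via the leading singular value


def _make_work(X):
    if isinstance(X, ExtendedMatrix):
        return _DenseWork(X.values)
    if isinstance(X, np.ndarray):
        return _DenseWork(X)
    if hasattr(X, "matvec") and hasattr(X, "rmatvec") and hasattr(X, "shape"):
        return _OpWork(X)
    raise TypeError(
        "X must be an ndarray, ExtendedMatrix, or expose shape/matvec/rmatvec"
    )


def _sign_fix(u, v):
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        return -u, -v
    return u, v


def _leading_triplet(work) -> tuple[NDArray, float, NDArray]:
    """Leading dense singular triplet of the current residual (deterministic)."""
    n, p = work.shape
    if isinstance(work, _DenseWork) and min(n, p) <= 3:
        U, s, Vt = np.linalg.svd(work.R, full_matrices=False)
        u, d, v = U[:, 0], float(s[0]), Vt[0]
    else:
        op = spla.LinearOperator(
            shape=(n, p), matvec=work.matvec, rmatvec=work.rmatvec, dtype=np.float64
        )
        v0 = np.random.default_rng(_INIT_SEED).standard_normal(min(n, p))
        U, s, Vt = spla.svds(op, k=1, v0=v0)
        u, d, v = U[:, 0], float(s[0]), Vt[0]
    u, v = _sign_fix(u, v)
    return u, d, v


def _apply_penalty(w, penalty: PenaltySpec):
    if penalty.degree is not None:
        return threshold_to_degree(w, penalty.degree, penalty.alpha)
    return en_threshold(w, penalty.lam, penalty.alpha)


def _en_penalty_value(v, lam, alpha) -> float:
    return lam * (
        alpha * float(np.sum(np.abs(v))) + 0.5 * (1 - alpha) * float(v @ v)
    )


# ---------------------------------------------------------------------------
# public operations


def dense_svd(X, K: int) -> SvdFactors:
    """Top-K dense singular triplets of X.

    For in-memory input this is a reference full SVD truncated to K; for
    matrix-free (chunked) input a Lanczos solver is used, which then requires
    ``K < min(n, P)``.
    """
    work = _make_work(X)
    n, p = work.shape
    if not 1 <= K <= min(n, p):
        raise ValueError(f"K must lie in [1, {min(n, p)}], got {K}")
    if isinstance(work, _DenseWork):
        U, s, Vt = np.linalg.svd(work.R, full_matrices=False)
        U, s, Vt = U[:, :K], s[:K], Vt[:K]
    else:
        if K >= min(n, p):
            raise ValueError("matrix-free dense_svd requires K < min(n, P)")
        op = spla.LinearOperator(
            shape=(n, p), matvec=work.matvec, rmatvec=work.rmatvec, dtype=np.float64
        )
        v0 = np.random.default_rng(_INIT_SEED).standard_normal(min(n, p))
        U, s, Vt = spla.svds(op, k=K, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    V = Vt.T.copy()
    for k in range(K):
        U[:, k], V[:, k] = _sign_fix(U[:, k], V[:, k])
    factors = SvdFactors(
        U=U,
        d=np.asarray(s, dtype=np.float64),
        V=V,
        nnz=np.count_nonzero(V, axis=0),
        penalty=None,
    )
    _attach_labels(factors, X)
    return factors


def rank1_ssvd(
    X,
    penalty: PenaltySpec,
    tol: float = 1e-6,
    max_iter: int = 1000,
    track_objective: bool = False,
) -> Rank1Result:
    """Leading penalized rank-1 factor of X by alternating iteration.

    Initialized at the leading dense singular pair, so with ``lam=0`` the
    dense leading triplet is reproduced. With a degree-parametrized penalty
    the returned ``v`` has exactly ``penalty.degree`` nonzeros (fewer only if
    ``X^T u`` has exact zeros). ``track_objective`` records the penalized
    least-squares objective after every iteration (in-memory,
    lam-parametrized fits only); it is non-increasing by construction.
    """
    work = _make_work(X)
    return _rank1_on_work(work, penalty, tol, max_iter, track_objective)


def _rank1_on_work(
    work,
    penalty: PenaltySpec,
    tol: float = 1e-6,
    max_iter: int = 1000,
    track_objective: bool = False,
    init: tuple | None = None,
) -> Rank1Result:
    if tol <= 0:
        raise ValueError("tol must be positive")
    if isinstance(work, _DenseWork) and work.is_zero():
        raise ValueError("matrix is identically zero")
    u, d0, v = init if init is not None else _leading_triplet(work)
    if d0 <= 0 or not np.isfinite(d0):
        raise ValueError("matrix is numerically zero (leading singular value 0)")
    track = track_objective and isinstance(work, _DenseWork) and penalty.lam is not None
    frob2 = work.frob2() if track else 0.0
    history: list[float] = []
    d = d0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = work.rmatvec(u)
        vt = _apply_penalty(w, penalty)
        nvt = np.linalg.norm(vt)
        if nvt == 0:
            raise ValueError(
                "penalty zeroed every loading; decrease lam or raise degree"
            )
        v_new = vt / nvt
        Xv = work.matvec(v_new)
        d = float(np.linalg.norm(Xv))
        if d == 0:
            raise ValueError("X v vanished during iteration; matrix is degenerate")
        u = Xv / d
        if track:
            lam = (
                penalty.lam
                if penalty.lam is not None
                else degree_lambda(w, penalty.degree, penalty.alpha)
            )
            history.append(
                frob2
                - 2.0 * d * float(np.linalg.norm(vt))  # -2 u^T X vtilde with u aligned
                + float(vt @ vt)
                + 2.0 * _en_penalty_value(vt, lam, penalty.alpha)
            )
        delta = float(np.linalg.norm(v_new - v)) / max(float(np.linalg.norm(v)), 1e-300)
        v = v_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"rank-1 sSVD did not converge in {max_iter} iterations "
            f"(last relative change {delta:.2e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    u, v = _sign_fix(u, v)
    return Rank1Result(
        u=u, d=d, v=v, converged=converged, n_iter=n_iter, objective_history=history
    )


def deflate(X: NDArray[np.float64], u, d, v) -> NDArray[np.float64]:
    """Subtract the rank-1 component ``d u v^T`` from X."""
    return np.asarray(X, dtype=np.float64) - float(d) * np.outer(u, v)


def _bic(rss: float, k: int, n: int, p: int) -> float:
    np_ = n * p
    return float(np.log(max(rss, 1e-300) / np_) + k * np.log(np_) / np_)


_FLAT_CURVE_MARGIN = 0.1  # log-RSS units; below this the curve is "flat"


def tune_degree(
    X,
    alpha: float,
    candidate_degrees,
    n_factors: int = 1,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> TuningResult:
    """Select the sparsity degree per factor by minimizing the rank-1 BIC.

    For each factor the current residual is fit at every candidate degree;
    the degree minimizing the BIC is selected (ties broken toward the
    smallest degree, i.e. parsimony), the factor is refit at that degree and
    deflated before tuning the next one. A flat criterion curve — no minimum
    materially below the densest candidate's fit — triggers
    :class:`FlatTuningCurveWarning`, the signature of a matrix without sparse
    low-rank structure.
    """
    grid = np.asarray(sorted(set(int(k) for k in np.asarray(candidate_degrees).ravel())))
    work = _make_work(X)
    n, p = work.shape
    if grid.size == 0:
        raise ValueError("candidate degree grid is empty")
    if grid[0] < 1 or grid[-1] > p:
        raise ValueError(f"candidate degrees must lie in [1, {p}]")
    if alpha <= 0:
        raise ValueError("degree tuning requires alpha > 0")
    crit = np.empty((n_factors, grid.size))
    log_rss = np.empty(grid.size)
    selected = np.empty(n_factors, dtype=int)
    for f in range(n_factors):
        frob2 = work.frob2()
        init = _leading_triplet(work)
        for j, k in enumerate(grid):
            res = _rank1_on_work(
                work, PenaltySpec(alpha=alpha, degree=int(k)), tol, max_iter, init=init
            )
            rss = frob2 - res.d**2
            log_rss[j] = np.log(max(rss, 1e-300))
            crit[f, j] = _bic(rss, int(k), n, p)
        best = int(np.argmin(crit[f]))  # argmin returns first = smallest degree
        selected[f] = grid[best]
        # flat curve: the fit barely improves with degree (no sparse structure)
        if log_rss.max() - log_rss.min() < _FLAT_CURVE_MARGIN:
            warnings.warn(
                f"factor {f + 1}: tuning criterion is flat (log-RSS range "
                f"{log_rss.max() - log_rss.min():.3g} across the degree grid); "
                "the selected degree is unreliable",
                FlatTuningCurveWarning,
                stacklevel=2,
            )
        res = _rank1_on_work(
            work, PenaltySpec(alpha=alpha, degree=int(selected[f])), tol, max_iter, init=init
        )
        work.deflate(res.u, res.d, res.v)
    return TuningResult(
        candidate_degrees=grid, criterion_values=crit, selected_degree=selected
    )


def default_degree_grid(p: int, n_points: int = 20) -> NDArray[np.int_]:
    """20 log-spaced integer degrees from 1 to P (deduplicated)."""
    return np.unique(
        np.round(np.geomspace(1, p, num=min(n_points, p))).astype(int)
    )


def decompose(
    X,
    K: int,
    penalty: PenaltySpec | str | None = "auto",
    tol: float = 1e-6,
    max_iter: int = 1000,
    candidate_degrees=None,
) -> tuple[SvdFactors, TuningResult | None]:
    """Extract K sparse factors by sequential rank-1 fits with deflation.

    ``penalty`` is a :class:`PenaltySpec`, ``"auto"`` (per-factor BIC tuning
    of the degree over ``candidate_degrees``, default 20 log-spaced values),
    or ``None`` for a purely dense decomposition. Returns the sparse factors
    (with the dense triplets from the initializations attached as
    ``factors.dense``) and the tuning grid when tuning was requested.
    """
    work = _make_work(X)
    n, p = work.shape
    if not 1 <= K <= min(n, p):
        raise ValueError(f"K must lie in [1, {min(n, p)}], got {K}")
    auto = penalty == "auto"
    if auto:
        grid = (
            default_degree_grid(p)
            if candidate_degrees is None
            else np.asarray(sorted(set(int(k) for k in candidate_degrees)))
        )
        alpha = 1.0
    elif penalty is None:
        penalty = PenaltySpec(alpha=1.0, lam=0.0)
    elif not isinstance(penalty, PenaltySpec):
        raise TypeError("penalty must be a PenaltySpec, 'auto', or None")

    us, ds, vs = [], [], []
    dense_us, dense_ds, dense_vs = [], [], []
    convs, iters = [], []
    crit_rows, sel = [], []
    for _ in range(K):
        init = _leading_triplet(work)
        dense_us.append(init[0])
        dense_ds.append(init[1])
        dense_vs.append(init[2])
        if auto:
            frob2 = work.frob2()
            row = np.empty(grid.size)
            for j, k in enumerate(grid):
                res = _rank1_on_work(
                    work, PenaltySpec(alpha=alpha, degree=int(k)), tol, max_iter, init=init
                )
                row[j] = _bic(frob2 - res.d**2, int(k), n, p)
            crit_rows.append(row)
            k_sel = int(grid[int(np.argmin(row))])
            sel.append(k_sel)
            fac_penalty = PenaltySpec(alpha=alpha, degree=k_sel)
        else:
            fac_penalty = penalty
        res = _rank1_on_work(work, fac_penalty, tol, max_iter, init=init)
        us.append(res.u)
        ds.append(res.d)
        vs.append(res.v)
        convs.append(res.converged)
        iters.append(res.n_iter)
        work.deflate(res.u, res.d, res.v)

    order = np.argsort(-np.asarray(ds), kind="stable")
    V = np.column_stack(vs)[:, order]
    dense = SvdFactors(
        U=np.column_stack(dense_us)[:, order],
        d=np.asarray(dense_ds)[order],
        V=np.column_stack(dense_vs)[:, order],
        nnz=np.count_nonzero(np.column_stack(dense_vs)[:, order], axis=0),
        penalty=None,
    )
    factors = SvdFactors(
        U=np.column_stack(us)[:, order],
        d=np.asarray(ds)[order],
        V=V,
        nnz=np.count_nonzero(V, axis=0),
        penalty=None if auto else penalty,
        converged=np.asarray(convs)[order],
        n_iter=np.asarray(iters)[order],
        dense=dense,
    )
    _attach_labels(factors, X)
    _attach_labels(dense, X)
    tuning = None
    if auto:
        tuning = TuningResult(
            candidate_degrees=grid,
            criterion_values=np.vstack(crit_rows)[order],
            selected_degree=np.asarray(sel)[order],
        )
    return factors, tuning


def _attach_labels(factors: SvdFactors, X) -> None:
    if isinstance(X, ExtendedMatrix):
        factors.sample_ids = list(X.sample_ids)
        factors.column_map = list(X.column_map)
    elif hasattr(X, "column_map") and getattr(X, "column_map", None):
        factors.column_map = list(X.column_map)
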