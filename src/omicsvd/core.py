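"""Elastic-net penalization operators shared by the sparse-SVD machinery.

The elastic net mixes a lasso (absolute value) and a ridge (squared) penalty
through a mixing weight ``alpha``; its proximal map soft-thresholds the input
by ``alpha * lam`` and then shrinks the survivors by ``1 + (1 - alpha) * lam``.
Sparsity can be requested either through the penalty magnitude ``lam`` or
through a *degree*: the exact number of coordinates to keep nonzero, which is
translated into a data-driven ``lam`` at apply time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["PenaltySpec", "en_threshold", "threshold_to_degree"]


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty, parametrized by magnitude or by sparsity degree.

    Parameters
    ----------
    alpha
        Mixing weight in ``[0, 1]`` between lasso (``alpha=1``) and ridge
        (``alpha=0``).
    lam
        Nonnegative penalty magnitude. Mutually exclusive with ``degree``.
    degree
        Target number of nonzero loadings (``>= 1``). Mutually exclusive with
        ``lam``. Requires ``alpha > 0`` unless the degree equals the vector
        length, since a pure ridge penalty cannot zero coordinates exactly.
    """

    alpha: float = 1.0
    lam: float | None = None
    degree: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if (self.lam is None) == (self.degree is None):
            raise ValueError("exactly one of lam/degree must be set")
        if self.lam is not None and self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")
        if self.degree is not None and self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")


def en_threshold(z: ArrayLike, lam: float, alpha: float) -> NDArray[np.float64]:
    """Elastic-net proximal map applied elementwise.

    ``out_i = sign(z_i) * max(|z_i| - alpha*lam, 0) / (1 + (1-alpha)*lam)``

    With ``alpha=1`` this is plain soft-thresholding; with ``alpha=0`` it is
    ridge shrinkage (no exact zeros). The map is a contraction and preserves
    signs.
    """
    if lam < 0:
        raise ValueError(f"lam must be nonnegative, got {lam}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    z = np.asarray(z, dtype=np.float64)
    shrunk = np.maximum(np.abs(z) - alpha * lam, 0.0)
    return np.sign(z) * shrunk / (1.0 + (1.0 - alpha) * lam)


def degree_lambda(z: ArrayLike, degree: int, alpha: float) -> float:
    """Penalty magnitude that keeps exactly ``degree`` coordinates nonzero.

    Returns the largest cutoff ``t`` such that soft-thresholding at ``t``,
    restricted to the top-``degree`` support, leaves ``degree`` coordinates
    nonzero; ``lam = t / alpha``. With distinct absolute values this is simply
    the ``(degree+1)``-th largest absolute value scaled by ``1/alpha``, and 0
    when ``degree`` equals the vector length.
    """
    z = np.asarray(z, dtype=np.float64)
    p = z.size
    _check_degree(p, degree, alpha)
    if degree == p:
        return 0.0
    absz = np.abs(z)
    m = _kept_min_abs(absz, degree)
    below = absz[absz < m]
    t = float(below.max()) if below.size else 0.0
    return t / alpha


def threshold_to_degree(
    z: ArrayLike, degree: int, alpha: float
) -> NDArray[np.float64]:
    """Apply the elastic-net map with ``lam`` tuned to a target nonzero count.

    The kept support is the ``degree`` largest entries by absolute value; ties
    at the cutoff are broken toward the smallest column index so the result is
    deterministic across platforms. Entries already exactly zero in ``z``
    cannot be made nonzero, so the output may have fewer than ``degree``
    nonzeros only in that degenerate case.
    """
    z = np.asarray(z, dtype=np.float64)
    p = z.size
    _check_degree(p, degree, alpha)
    if degree == p:
        return z.copy()
    absz = np.abs(z)
    # abs descending, index ascending among ties
    order = np.lexsort((np.arange(p), -absz))
    support = order[:degree]
    lam = degree_lambda(z, degree, alpha)
    out = np.zeros(p)
    out[support] = en_threshold(z[support], lam, alpha)
    return out


def _check_degree(p: int, degree: int, alpha: float) -> None:
    if not 1 <= degree <= p:
        raise ValueError(f"degree must lie in [1, {p}], got {degree}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if alpha == 0.0 and degree < p:
        raise ValueError(
            "alpha=0 (pure ridge) cannot produce exact zeros; "
            "degree-parametrization requires alpha > 0"
        )


def _kept_min_abs(absz: NDArray[np.float64], degree: int) -> float:
    # smallest absolute value inside the kept top-`degree` support
    part = np.partition(absz, absz.size - degree)
    return float(part[absz.size - degree])
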