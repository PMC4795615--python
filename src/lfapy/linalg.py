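"""Truncated SVD primitive shared by both frequency estimators.

Both estimation algorithms only need the top few singular triplets of a
tall matrix (the number of latent dimensions d is far smaller than the
number of individuals n), so for large inputs a Lanczos-type iterative
solver (scipy's ARPACK-backed ``svds``) is used; below a size threshold a
dense LAPACK SVD is used instead.  Correctness is defined by the dense
result: the iterative path must match it up to per-column sign.

Sign convention: each right singular vector is flipped so that its entry
of largest magnitude is positive, removing the SVD sign ambiguity so that
repeated runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds

_ORTHO_TOL = 1e-8


@dataclass
class TruncatedSVDResult:
    """Top-k singular triplets of a real matrix.

    left_vectors : (m, k) orthonormal columns.
    singular_values : (k,) nonnegative, nonincreasing.
    right_vectors : (n, k) orthonormal columns.
    """

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray

    @property
    def k(self) -> int:
        return self.singular_values.shape[0]

    def reconstruct(self) -> np.ndarray:
        """The best rank-k approximation U diag(s) V^T."""
        return (self.left_vectors * self.singular_values) @ self.right_vectors.T


def _fix_signs(U: np.ndarray, V: np.ndarray) -> None:
    """Make each right vector's largest-magnitude entry positive, in place."""
    for c in range(V.shape[1]):
        col = V[:, c]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            V[:, c] = -col
            U[:, c] = -U[:, c]


def truncated_svd(
    M: np.ndarray,
    k: int,
    seed: int = 0,
    dense_threshold: int = 500,
    tol: float = 1e-10,
) -> TruncatedSVDResult:
    """Compute the top-k singular triplets of ``M``.

    Parameters
    ----------
    M : (m, n) real matrix with finite entries.
    k : number of singular triplets, 1 <= k <= min(m, n).
    seed : seeds the Lanczos starting vector so iterative runs are
        reproducible; ignored on the dense path.
    dense_threshold : use the dense LAPACK SVD when min(m, n) is at or
        below this size (the iterative solver pays off only on large
        problems).
    tol : convergence tolerance on singular-value residuals for the
        iterative solver.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("expected a 2-d matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix entries must be finite")
    m, n = M.shape
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")

    # ARPACK requires k strictly below min(m, n).
    if min(m, n) <= dense_threshold or k >= min(m, n):
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        U, s, V = U[:, :k].copy(), s[:k].copy(), Vt[:k].T.copy()
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(m, n))
        U, s, Vt = svds(M, k=k, tol=tol, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, V = U[:, order], s[order], Vt[order].T
        U, V = np.ascontiguousarray(U), np.ascontiguousarray(V)
    _fix_signs(U, V)
    return TruncatedSVDResult(U, s, V)
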