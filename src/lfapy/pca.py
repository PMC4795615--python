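"""PCA-based estimation of individual-specific allele frequencies (Model 1).

Model 1 writes the m x n allele-frequency matrix as F = Gamma S with a
d x n real basis S whose last row is the constant 1 (so d = 1 means no
structure and row i of F collapses to the SNP's marginal frequency).  The
estimator projects the row-centered genotype matrix onto its top d-1
right singular vectors, adds the row means back, scales by 1/2, and
truncates the result into [C, 1-C]; C defaults to 1/(2n), the smallest
frequency resolvable from 2n observed alleles.

The pre-truncation estimate F* is unconstrained and can leave [0, 1];
that is the documented drawback motivating the logistic-factor estimator
in :mod:`lfapy.lfa`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import AlleleFreqMatrix, GenotypeMatrix
from .linalg import truncated_svd


def _as_numeric(X) -> np.ndarray:
    """Accept a GenotypeMatrix or a (possibly fractional) numeric array.

    Missing entries are NaN on the numeric path.  Fractional values are
    allowed here on purpose: noiseless simulation harnesses feed 2F
    directly through the same linear-algebra path.
    """
    if isinstance(X, GenotypeMatrix):
        return X.as_float()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("genotype input must be 2-dimensional")
    return X


def center_rows(X) -> tuple[np.ndarray, np.ndarray]:
    """Row-center a genotype matrix, mean-imputing missing entries.

    Returns ``(X_star, mu)`` where ``mu[i]`` is the mean over non-missing
    entries of row i and ``X_star`` has those means subtracted with missing
    entries set to 0 (i.e. imputed at the row mean).

    Raises on any all-missing row.
    """
    X = _as_numeric(X)
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs == 0):
        bad = int(np.argwhere(n_obs == 0)[0, 0])
        raise ValueError(f"row {bad} has no non-missing genotypes")
    with np.errstate(invalid="ignore"):
        mu = np.nansum(X, axis=1) / n_obs
    X_star = np.where(obs, X - mu[:, None], 0.0)
    return X_star, mu


@dataclass
class Model1Fit:
    """Output of the PCA frequency estimator.

    F_tilde : truncated estimate, entries in [C, 1-C].
    F_star : pre-truncation estimate Gamma_tilde @ S_tilde (may exit [0,1]).
    Gamma_tilde : (m, d) loadings; last column is mu/2.
    S_tilde : (d, n) basis; last row all ones.
    mu : per-SNP genotype row means.
    """

    F_tilde: AlleleFreqMatrix
    F_star: np.ndarray
    Gamma_tilde: np.ndarray
    S_tilde: np.ndarray
    mu: np.ndarray
    C: float
    d: int


class PCAAlleleFrequencies(BaseEstimator):
    """Estimate individual-specific allele frequencies by projection onto
    principal components.

    Parameters
    ----------
    n_components : int, default 2
        Model dimension d (number of basis rows including the intercept
        row); d - 1 principal components are used.
    truncation : float or None, default None
        Truncation constant C in (0, 1/2); None means 1/(2n).
    svd_seed : int, default 0
        Seed for the iterative SVD starting vector.
    dense_threshold : int, default 500
        Matrix size below which the dense SVD path is used.

    Attributes (after fit)
    ----------------------
    F_ : (m, n) truncated frequency estimates in [C, 1-C].
    F_star_ : (m, n) pre-truncation estimates.
    basis_ : (d, n) estimated basis S-tilde, last row ones.
    loadings_ : (m, d) loadings Gamma-tilde, last column mu/2.
    mean_ : (m,) genotype row means.
    truncation_ : the C actually used.
    """

    def __init__(self, n_components=2, truncation=None, svd_seed=0, dense_threshold=500):
        self.n_components = n_components
        self.truncation = truncation
        self.svd_seed = svd_seed
        self.dense_threshold = dense_threshold

    def fit(self, X, y=None):
        X_num = _as_numeric(X)
        m, n = X_num.shape
        d = int(self.n_components)
        if d < 1:
            raise ValueError(f"n_components must be >= 1, got {d}")
        if d > n:
            raise ValueError(f"n_components={d} exceeds the number of individuals {n}")
        C = 1.0 / (2.0 * n) if self.truncation is None else float(self.truncation)
        if not 0.0 < C < 0.5:
            raise ValueError(f"truncation must lie in (0, 1/2), got {C}")

        X_star, mu = center_rows(X_num)
        ones = np.ones((1, n))
        if d == 1:
            Gamma = (mu / 2.0)[:, None]
            S = ones
        else:
            svd = truncated_svd(
                X_star, d - 1, seed=self.svd_seed, dense_threshold=self.dense_threshold
            )
            Gamma = np.hstack(
                [svd.left_vectors * svd.singular_values / 2.0, (mu / 2.0)[:, None]]
            )
            S = np.vstack([svd.right_vectors.T, ones])
        F_star = Gamma @ S
        F = np.clip(F_star, C, 1.0 - C)

        self.F_ = F
        self.F_star_ = F_star
        self.basis_ = S
        self.loadings_ = Gamma
        self.mean_ = mu
        self.truncation_ = C
        self.n_features_in_ = n
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the truncated frequency estimates F_."""
        return self.fit(X).F_


def pca_allele_freq(X, d: int, C: float = None, svd_seed: int = 0) -> Model1Fit:
    """Functional wrapper over :class:`PCAAlleleFrequencies`."""
    est = PCAAlleleFrequencies(n_components=d, truncation=C, svd_seed=svd_seed).fit(X)
    snp_ids = X.snp_ids if isinstance(X, GenotypeMatrix) else None
    sample_ids = X.sample_ids if isinstance(X, GenotypeMatrix) else None
    F = AlleleFreqMatrix(est.F_, provenance="pca", snp_ids=snp_ids, sample_ids=sample_ids)
    return Model1Fit(
        F_tilde=F,
        F_star=est.F_star_,
        Gamma_tilde=est.loadings_,
        S_tilde=est.basis_,
        mu=est.mean_,
        C=est.truncation_,
        d=d,
    )
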