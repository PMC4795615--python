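"""Logistic factor analysis (Model 2) of SNP genotype matrices.

Model 2 parameterizes the logit of the individual-specific allele
frequencies as L = A H, where H is a d x n matrix of "logistic factors"
whose last row is the constant 1 (the intercept) and A holds per-SNP
coefficients.  Estimation proceeds in two stages:

1. Factor estimation: run the PCA projection of :mod:`lfapy.pca`, keep
   the rows of the pre-truncation estimate whose entries all lie strictly
   inside (C, 1-C) (where the logit is numerically stable), logit-transform
   that submatrix, standardize each row, and take its top d-1 right
   singular vectors stacked on the ones row as H-hat.
2. Per-SNP Binomial(2, pi) logistic regression of genotypes on the rows
   of H-hat by Newton/IRLS with step-halving, giving A-hat, the logit
   matrix L-hat = A-hat @ H-hat and F-hat = expit(L-hat).

Unlike the PCA estimate, every fitted frequency lies strictly inside
(0, 1) because the natural parameter is modeled directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .io import AlleleFreqMatrix, GenotypeMatrix, LogitFreqMatrix
from .linalg import truncated_svd
from .pca import PCAAlleleFrequencies, _as_numeric


@dataclass
class LogisticFactors:
    """Estimated logistic factors H-hat.

    H : (d, n); last row is all ones, the first d-1 rows are orthonormal
    right singular vectors of the standardized logit submatrix.
    """

    H: np.ndarray
    d: int
    subset_size: int
    C: float

    @property
    def n(self) -> int:
        return self.H.shape[1]


@dataclass
class RowSubset:
    """SNP rows whose pre-truncation frequencies all lie in (C, 1-C)."""

    indices: np.ndarray
    fallback: bool = False

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class SnpFit:
    """Single-SNP logistic regression result."""

    coef: np.ndarray
    deviance_residual: float
    loglik: float
    converged: bool
    separated: bool


@dataclass
class Model2Fit:
    """Output of the LFA frequency estimator."""

    A_hat: np.ndarray
    H: LogisticFactors
    L_hat: LogitFreqMatrix
    F_hat: AlleleFreqMatrix
    converged: np.ndarray
    separation_flag: np.ndarray
    d: int
    C: float


# ---------------------------------------------------------------------------
# Binomial(2, .) logistic regression, vectorized across SNPs


def _masked_loglik(A, H, Xf, obs):
    """log-likelihood per SNP: sum_j x eta - 2 log(1 + exp(eta)) over observed j."""
    eta = A @ H
    terms = Xf * eta - 2.0 * np.logaddexp(0.0, eta)
    return np.where(obs, terms, 0.0).sum(axis=1)


def binomial_logistic_mle(
    X,
    H: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    coef_cap: float = 30.0,
):
    """Per-SNP maximum likelihood for x_ij ~ Binomial(2, expit(a_i . h_j)).

    ``X`` is (m, n) with NaN for missing entries (dropped from that SNP's
    likelihood); ``H`` is the (d, n) factor matrix whose last row must be
    the intercept ones.  Newton steps with step-halving; if any coefficient
    exceeds ``coef_cap`` in magnitude (perfect separation / monomorphic
    SNPs) the SNP is flagged, its coefficients are clipped to the cap and
    iteration stops for that SNP.

    Returns ``(A, loglik, converged, separated)``.
    """
    X = np.asarray(X, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if not np.all(np.isfinite(H)):
        raise ValueError("factor matrix H must be finite")
    d, n = H.shape
    m = X.shape[0]
    if X.shape[1] != n:
        raise ValueError("genotypes and factors disagree on the number of individuals")
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs < d):
        bad = int(np.argwhere(n_obs < d)[0, 0])
        raise ValueError(f"SNP row {bad} has fewer non-missing genotypes than d={d}")
    Xf = np.where(obs, X, 0.0)

    # Start from the intercept-only MLE logit(mean(x)/2).
    p0 = Xf.sum(axis=1) / (2.0 * n_obs)
    A = np.zeros((m, d))
    with np.errstate(divide="ignore"):
        A[:, -1] = np.clip(logit(p0), -coef_cap, coef_cap)
    separated = (p0 <= 0.0) | (p0 >= 1.0)
    converged = np.zeros(m, dtype=bool)
    ll = _masked_loglik(A, H, Xf, obs)

    eye = np.eye(d) * 1e-12
    for _ in range(max_iter):
        active = ~(converged | separated)
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ha = H
        Aa = A[idx]
        Xa, obsa = Xf[idx], obs[idx]
        eta = Aa @ Ha
        pi = expit(eta)
        resid = np.where(obsa, Xa - 2.0 * pi, 0.0)
        grad = resid @ Ha.T
        W = np.where(obsa, 2.0 * pi * (1.0 - pi), 0.0)
        hess = np.einsum("kj,ij,lj->ikl", Ha, W, Ha, optimize=True) + eye
        try:
            delta = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(h, g, rcond=None)[0] for h, g in zip(hess, grad)])

        # Step-halving on SNPs whose likelihood would decrease.
        step = np.ones(len(idx))
        new_A = Aa + delta
        new_ll = _masked_loglik(new_A, Ha, Xa, obsa)
        for _half in range(30):
            worse = new_ll < ll[idx] - 1e-13
            if not worse.any():
                break
            step[worse] *= 0.5
            new_A[worse] = Aa[worse] + step[worse, None] * delta[worse]
            new_ll[worse] = _masked_loglik(new_A[worse], Ha, Xa[worse], obsa[worse])

        over = np.max(np.abs(new_A), axis=1) > coef_cap
        new_A[over] = np.clip(new_A[over], -coef_cap, coef_cap)
        done = np.abs(new_ll - ll[idx]) < tol
        A[idx] = new_A
        ll[idx] = _masked_loglik(new_A, Ha, Xa, obsa)
        separated[idx[over]] = True
        converged[idx[done & ~over]] = True

    return A, ll, converged, separated


def _saturated_loglik(x: np.ndarray) -> float:
    """Saturated Binomial(2, .) log-likelihood (binomial coefficient dropped)."""
    x = x[np.isfinite(x)]
    p = x / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = x * np.where(p > 0, np.log(p), 0.0) + (2 - x) * np.where(p < 1, np.log1p(-p), 0.0)
    return float(t.sum())


def fit_snp_logistic(
    x,
    H: LogisticFactors | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    coef_cap: float = 30.0,
) -> SnpFit:
    """Fit a single SNP's genotypes on the logistic factors.

    Returns the coefficient vector, the residual deviance
    2 (loglik_saturated - loglik_fit), and convergence/separation flags.
    """
    Hm = H.H if isinstance(H, LogisticFactors) else np.asarray(H, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    A, ll, conv, sep = binomial_logistic_mle(
        x, Hm, max_iter=max_iter, tol=tol, coef_cap=coef_cap
    )
    dev = max(0.0, 2.0 * (_saturated_loglik(x[0]) - float(ll[0])))
    return SnpFit(
        coef=A[0],
        deviance_residual=dev,
        loglik=float(ll[0]),
        converged=bool(conv[0]),
        separated=bool(sep[0]),
    )


# ---------------------------------------------------------------------------
# Factor estimation (Algorithm stage 1)


def select_row_subset(F_star: np.ndarray, C: float, d: int) -> RowSubset:
    """Rows of the pre-truncation estimate where the logit is stable.

    Primary rule: every entry strictly inside (C, 1-C).  If fewer than
    max(d, 10) rows qualify, fall back to ranking rows by their margin
    min_j min(pi*_ij, 1 - pi*_ij) and keeping the top max(10 d, 100) rows
    with positive margin (enough to span the factor row space).  Rows whose
    logit values have zero variance are excluded either way.
    """
    m = F_star.shape[0]
    margin = np.min(np.minimum(F_star, 1.0 - F_star), axis=1)
    inside = (F_star > C).all(axis=1) & (F_star < 1.0 - C).all(axis=1)
    sd_ok = np.zeros(m, dtype=bool)
    pos = margin > 0
    if pos.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = logit(np.clip(F_star[pos], 1e-300, 1 - 1e-16))
        sd_ok[pos] = lg.std(axis=1, ddof=1) > 0
    keep = inside & sd_ok
    if keep.sum() >= max(d, 10):
        return RowSubset(np.flatnonzero(keep))
    candidates = np.flatnonzero(pos & sd_ok)
    order = candidates[np.argsort(-margin[candidates], kind="stable")]
    top = order[: max(10 * d, 100)]
    if len(top) < max(d, 10):
        raise ValueError(
            f"only {len(top)} usable rows for factor estimation; need {max(d, 10)}"
        )
    return RowSubset(np.sort(top), fallback=True)


def estimate_logistic_factors(
    X, d: int, C: float = None, svd_seed: int = 0
) -> LogisticFactors:
    """Estimate the d x n logistic factor matrix H-hat from genotypes."""
    X_num = _as_numeric(X)
    m, n = X_num.shape
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if d > n:
        raise ValueError(f"d={d} exceeds the number of individuals {n}")
    C_val = 1.0 / (2.0 * n) if C is None else float(C)
    if not 0.0 < C_val < 0.5:
        raise ValueError(f"C must lie in (0, 1/2), got {C_val}")
    ones = np.ones((1, n))
    if d == 1:
        return LogisticFactors(H=ones, d=1, subset_size=0, C=C_val)

    pca = PCAAlleleFrequencies(n_components=d, truncation=C_val, svd_seed=svd_seed).fit(X_num)
    subset = select_row_subset(pca.F_star_, C_val, d)
    L_S = logit(pca.F_star_[subset.indices])
    L_S = L_S - L_S.mean(axis=1, keepdims=True)
    L_S = L_S / L_S.std(axis=1, ddof=1, keepdims=True)
    svd = truncated_svd(L_S, d - 1, seed=svd_seed)
    H = np.vstack([svd.right_vectors.T, ones])
    return LogisticFactors(H=H, d=d, subset_size=len(subset), C=C_val)


# ---------------------------------------------------------------------------
# Estimator


class LogisticFactorAnalysis(BaseEstimator):
    """Logistic factor analysis of a SNP genotype matrix.

    Parameters
    ----------
    n_components : int, default 2
        Model dimension d, including the intercept factor.
    truncation : float or None, default None
        Stability threshold C in (0, 1/2) for the logit subset; None
        means 1/(2n).
    max_iter, tol : IRLS iteration cap and log-likelihood tolerance.
    coef_cap : float, default 30.0
        Magnitude cap flagging separated/monomorphic SNPs (logit 30 is
        within 1e-13 of the boundary frequency).
    svd_seed : int, default 0
        Seed for the iterative SVD starting vectors.

    Attributes (after fit)
    ----------------------
    factors_ : (d, n) logistic factors H-hat, last row ones.
    coef_ : (m, d) per-SNP coefficients A-hat, last column the intercept.
    L_ : (m, n) fitted logits A-hat @ H-hat.
    F_ : (m, n) fitted frequencies expit(L_), strictly inside (0, 1).
    converged_, separated_ : per-SNP flags.
    subset_size_ : rows used for factor estimation.
    """

    def __init__(
        self,
        n_components=2,
        truncation=None,
        max_iter=100,
        tol=1e-10,
        coef_cap=30.0,
        svd_seed=0,
    ):
        self.n_components = n_components
        self.truncation = truncation
        self.max_iter = max_iter
        self.tol = tol
        self.coef_cap = coef_cap
        self.svd_seed = svd_seed

    def fit(self, X, y=None):
        X_num = _as_numeric(X)
        factors = estimate_logistic_factors(
            X_num, int(self.n_components), C=self.truncation, svd_seed=self.svd_seed
        )
        A, ll, conv, sep = binomial_logistic_mle(
            X_num,
            factors.H,
            max_iter=self.max_iter,
            tol=self.tol,
            coef_cap=self.coef_cap,
        )
        self.factors_ = factors.H
        self.factors_info_ = factors
        self.coef_ = A
        self.loglik_ = ll
        self.L_ = A @ factors.H
        self.F_ = expit(self.L_)
        self.converged_ = conv
        self.separated_ = sep
        self.subset_size_ = factors.subset_size
        self.truncation_ = factors.C
        self.n_features_in_ = X_num.shape[1]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the frequency estimates F_."""
        return self.fit(X).F_


def lfa_allele_freq(
    X, d: int, C: float = None, svd_seed: int = 0, **irls_kwargs
) -> Model2Fit:
    """Functional wrapper over :class:`LogisticFactorAnalysis`."""
    est = LogisticFactorAnalysis(
        n_components=d, truncation=C, svd_seed=svd_seed, **irls_kwargs
    ).fit(X)
    snp_ids = X.snp_ids if isinstance(X, GenotypeMatrix) else None
    sample_ids = X.sample_ids if isinstance(X, GenotypeMatrix) else None
    return Model2Fit(
        A_hat=est.coef_,
        H=est.factors_info_,
        L_hat=LogitFreqMatrix(est.L_),
        F_hat=AlleleFreqMatrix(
            est.F_, provenance="lfa", snp_ids=snp_ids, sample_ids=sample_ids
        ),
        converged=est.converged_,
        separation_flag=est.separated_,
        d=d,
        C=est.truncation_,
    )
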