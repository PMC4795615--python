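"""Downstream statistics on fitted population structure.

Four tools built on the logistic-factor machinery:

- per-SNP deviance comparing the structured logistic fit against the
  intercept-only fit, and the induced differentiation ranking;
- a goodness-of-fit test of Hardy-Weinberg equilibrium conditional on
  structure (genotype classes 0/1/2 against probabilities
  (1-pi)^2, 2 pi (1-pi), pi^2 per individual);
- a structural F_ST analogue, the variance of a SNP's individual-specific
  frequencies over its heterozygosity pi-bar (1 - pi-bar);
- model-dimension selection by parametric-bootstrap calibration of the
  HWE statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .lfa import (
    LogisticFactors,
    LogisticFactorAnalysis,
    binomial_logistic_mle,
    fit_snp_logistic,
)
from .pca import _as_numeric


@dataclass
class DifferentiationResult:
    """Per-SNP structure differentiation by deviance."""

    snp_id: str
    deviance: float
    df: int
    rank: int = 0
    maf: float = float("nan")
    separated: bool = False


@dataclass
class GofResult:
    """Conditional-HWE goodness of fit for one SNP."""

    snp_id: str
    statistic: float
    expected_counts: np.ndarray
    observed_counts: np.ndarray


def _intercept_only_loglik(x: np.ndarray) -> float:
    """Closed-form intercept-only Binomial(2, p) log-likelihood at the MLE."""
    x = x[np.isfinite(x)]
    n = x.size
    s = float(x.sum())
    p = s / (2.0 * n)
    ll = 0.0
    if p > 0:
        ll += s * np.log(p)
    if p < 1:
        ll += (2.0 * n - s) * np.log1p(-p)
    return ll


def snp_deviance(x, H: LogisticFactors, snp_id: str = "snp", **fit_kwargs) -> DifferentiationResult:
    """Deviance of the structured logistic fit versus intercept-only.

    deviance = 2 [loglik(logit pi = sum_k a_k h_k) - loglik(logit pi = a_d)],
    nonnegative, with d - 1 degrees of freedom; 0 when d = 1 since the two
    models coincide.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    d = H.d if isinstance(H, LogisticFactors) else np.asarray(H).shape[0]
    if d == 1:
        obs = np.isfinite(x)
        p = float(np.mean(x[obs])) / 2.0
        return DifferentiationResult(snp_id, 0.0, 0, maf=min(p, 1 - p))
    fit = fit_snp_logistic(x, H, **fit_kwargs)
    ll0 = _intercept_only_loglik(x)
    dev = max(0.0, 2.0 * (fit.loglik - ll0))
    obs = np.isfinite(x)
    p = float(np.mean(x[obs])) / 2.0
    return DifferentiationResult(
        snp_id, dev, d - 1, maf=min(p, 1 - p), separated=fit.separated
    )


def rank_snps(X, H: LogisticFactors, **fit_kwargs) -> list[DifferentiationResult]:
    """Rank all SNPs by descending deviance (ties broken by snp_id).

    The per-SNP logistic fits are vectorized; the result is a permutation
    of the input SNP set with 1-based ranks, deterministic for equal
    inputs.
    """
    snp_ids = X.snp_ids if isinstance(X, GenotypeMatrix) else None
    X_num = _as_numeric(X)
    m = X_num.shape[0]
    if snp_ids is None:
        snp_ids = [f"snp_{i}" for i in range(m)]
    Hm = H.H if isinstance(H, LogisticFactors) else np.asarray(H, dtype=np.float64)
    d = Hm.shape[0]
    obs = np.isfinite(X_num)
    p = np.nansum(X_num, axis=1) / (2.0 * obs.sum(axis=1))
    maf = np.minimum(p, 1.0 - p)
    if d == 1:
        dev = np.zeros(m)
        sep = np.zeros(m, dtype=bool)
    else:
        _, ll, _, sep = binomial_logistic_mle(X_num, Hm, **fit_kwargs)
        ll0 = np.array([_intercept_only_loglik(X_num[i]) for i in range(m)])
        dev = np.maximum(0.0, 2.0 * (ll - ll0))
    order = sorted(range(m), key=lambda i: (-dev[i], snp_ids[i]))
    results = [None] * m
    for pos, i in enumerate(order, start=1):
        results[pos - 1] = DifferentiationResult(
            snp_ids[i], float(dev[i]), d - 1, rank=pos, maf=float(maf[i]),
            separated=bool(sep[i]),
        )
    return results


def hwe_gof(x, pi, snp_id: str = "snp") -> GofResult:
    """Goodness of fit of genotype counts to HWE conditional on structure.

    For genotype classes g in {0, 1, 2} with per-individual probabilities
    (1-pi_j)^2, 2 pi_j (1-pi_j), pi_j^2 (x counts the frequency-pi allele),
    compares observed class counts against expected counts summed over
    individuals with a Pearson chi-square statistic.  An empty expected
    class with observed members yields +inf.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    pi = np.asarray(pi, dtype=np.float64).ravel()
    if x.shape != pi.shape:
        raise ValueError("genotypes and frequencies must have equal length")
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    obs_mask = np.isfinite(x)
    if not obs_mask.any():
        raise ValueError("no non-missing genotypes")
    x, pi = x[obs_mask], pi[obs_mask]
    probs = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2])
    expected = probs.sum(axis=1)
    observed = np.array([(x == g).sum() for g in (0, 1, 2)], dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    if np.any((expected == 0) & (observed > 0)):
        stat = float("inf")
    else:
        stat = float(np.where(expected > 0, terms, 0.0).sum())
    return GofResult(snp_id, stat, expected, observed)


def _hwe_stats_matrix(X_num: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP HWE statistics (NaN genotypes dropped per SNP)."""
    obs = np.isfinite(X_num)
    probs0 = np.where(obs, (1 - F) ** 2, 0.0).sum(axis=1)
    probs1 = np.where(obs, 2 * F * (1 - F), 0.0).sum(axis=1)
    probs2 = np.where(obs, F**2, 0.0).sum(axis=1)
    E = np.stack([probs0, probs1, probs2], axis=1)
    O = np.stack([np.where(obs, X_num == g, False).sum(axis=1) for g in (0, 1, 2)], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(E > 0, (O - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    stats = terms.sum(axis=1)
    stats[np.any((E == 0) & (O > 0), axis=1)] = np.inf
    return stats


def structural_fst(pi) -> float:
    """Structural F_ST analogue for one SNP.

    Var_j(pi_ij) / (pi-bar (1 - pi-bar)) with the population (1/n)
    variance; returns 0 when the mean frequency is 0 or 1.  Bounded in
    [0, 1] for frequencies in [0, 1]; reaches 1 only at full fixation
    (all frequencies 0 or 1 with both present).
    """
    pi = np.asarray(pi, dtype=np.float64).ravel()
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    mean = pi.mean()
    denom = mean * (1.0 - mean)
    if denom == 0.0:
        return 0.0
    return float(pi.var(ddof=0) / denom)


def select_dimension(X, d_candidates, C: float = None, seed: int = 0, **lfa_kwargs):
    """Choose the model dimension d by penalized goodness of fit.

    Each candidate d is scored by the mean per-SNP residual deviance of
    its LFA fit plus a BIC complexity penalty of d log(n) (each SNP's
    logistic regression spends d parameters on n individuals).  Missing
    structure dimensions leave large residual deviance, so the score drops
    steeply up to the generating d; beyond it an extra factor buys only
    the spurious in-sample gain of fitting noise (of order
    (1 + sqrt(n/m))^2 per dimension), which is well below the log(n)
    penalty — hence the score turns upward and the minimum sits at the
    generating dimension.  Ties go to the smallest d.

    The mean conditional-HWE statistic of each fit is reported alongside
    as a model-diagnostic column (non-finite per-SNP statistics excluded).

    Returns ``(d_best, scores)`` with one scores row per candidate:
    ``d``, ``mean_deviance``, ``bic``, ``mean_hwe_stat``.
    """
    X_num = _as_numeric(X)
    m, n = X_num.shape
    d_candidates = sorted(int(d) for d in d_candidates)
    if not d_candidates:
        raise ValueError("no candidate dimensions supplied")
    if d_candidates[0] < 1 or d_candidates[-1] > n:
        raise ValueError("candidates must lie in [1, n]")
    from .lfa import _saturated_loglik

    sat = np.array([_saturated_loglik(X_num[i]) for i in range(m)])
    rows = []
    for d in d_candidates:
        fit = LogisticFactorAnalysis(
            n_components=d, truncation=C, svd_seed=seed, **lfa_kwargs
        ).fit(X_num)
        mean_dev = float(np.mean(2.0 * (sat - fit.loglik_)))
        hwe = _hwe_stats_matrix(X_num, fit.F_)
        hwe = hwe[np.isfinite(hwe)]
        rows.append(
            {
                "d": d,
                "mean_deviance": mean_dev,
                "bic": mean_dev + d * np.log(n),
                "mean_hwe_stat": float(hwe.mean()) if hwe.size else float("nan"),
            }
        )
    scores = pd.DataFrame(rows)
    d_best = int(scores.loc[scores["bic"].idxmin(), "d"])
    return d_best, scores
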