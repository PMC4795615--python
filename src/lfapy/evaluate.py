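"""Accuracy metrics for structure bases and frequency estimates.

Two families of metrics: mean R-squared from regressing each true
(logit-)frequency row on an estimated factor basis (basis recovery), and
entrywise error metrics between a true and an estimated frequency matrix
(Kullback-Leibler divergence between the implied Binomial(2, .) laws,
mean absolute error, root mean squared error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .io import AlleleFreqMatrix


@dataclass
class BasisRecoveryScore:
    """Mean and per-SNP R-squared of true rows regressed on a basis."""

    mean_r2: float
    per_snp_r2: np.ndarray
    scale: str


@dataclass
class FreqErrorScore:
    """Entrywise error metrics between frequency matrices."""

    kl: float
    mae: float
    rmse: float


def _values(F) -> np.ndarray:
    return np.asarray(F.values if isinstance(F, AlleleFreqMatrix) else F, dtype=np.float64)


def mean_r2_basis(F_true, basis, scale: str = "freq") -> BasisRecoveryScore:
    """Regress each row of F (or logit F) on the basis rows; average R^2.

    The basis's ones row serves as the intercept (one is appended when
    absent).  R^2 = 1 - RSS/TSS per SNP with TSS about the row mean;
    constant rows (TSS = 0) count as perfectly explained, R^2 = 1.
    """
    Y = _values(F_true)
    B = np.asarray(basis, dtype=np.float64)
    if B.ndim != 2 or B.shape[1] != Y.shape[1]:
        raise ValueError("basis must be d x n matching the frequency matrix")
    if np.linalg.matrix_rank(B) < 1:
        raise ValueError("basis must have rank >= 1")
    if scale == "logit":
        if np.any(Y <= 0) or np.any(Y >= 1):
            raise ValueError("logit scale requires frequencies strictly in (0, 1)")
        Y = logit(Y)
    elif scale != "freq":
        raise ValueError(f"unknown scale {scale!r}")
    n = Y.shape[1]
    has_ones = np.any(np.all(np.isclose(B, B[:, :1]) & (np.abs(B) > 0), axis=1))
    if not has_ones:
        B = np.vstack([B, np.ones(n)])
    D = B.T  # n x d design
    coef, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    resid = Y.T - D @ coef
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - rss / tss
    r2 = np.where(tss <= 1e-12 * np.maximum(1.0, (Y**2).sum(axis=1)), 1.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    return BasisRecoveryScore(mean_r2=float(r2.mean()), per_snp_r2=r2, scale=scale)


def freq_error(F_true, F_hat) -> FreqErrorScore:
    """Entrywise KL / MAE / RMSE between true and estimated frequencies.

    The KL term is the divergence between Binomial(2, pi) and
    Binomial(2, pi-hat) laws, 2 [pi log(pi/pi-hat) + (1-pi) log((1-pi)/(1-pi-hat))],
    with the 0 log 0 = 0 convention; the estimate must lie strictly inside
    (0, 1) for the KL to be finite.
    """
    T = _values(F_true)
    E = _values(F_hat)
    if T.shape != E.shape:
        raise ValueError("frequency matrices must have equal shape")
    diff = T - E
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(T > 0, T * (np.log(T) - np.log(E)), 0.0)
        term0 = np.where(T < 1, (1 - T) * (np.log1p(-T) - np.log1p(-E)), 0.0)
    kl = float(np.mean(2.0 * (term1 + term0)))
    return FreqErrorScore(kl=kl, mae=mae, rmse=rmse)
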