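"""Synthetic structured allele-frequency matrices and Binomial genotypes.

Four structure generators produce a truth matrix F of individual-specific
allele frequencies, each a pure function of its seed:

- ``simulate_bn``: K discrete subpopulations with Balding-Nichols
  Beta-distributed frequencies around Uniform(0.1, 0.9) ancestral
  frequencies (spread governed by fst);
- ``simulate_psd``: the admixture model F = P Q with Dirichlet(alpha)
  admixture proportions and Balding-Nichols ancestral population
  frequencies P;
- ``simulate_spatial``: a rank-3 smooth positional construction (the
  factor rows are an orthogonalized quadratic in position), intensity a
  scaling the non-intercept loadings;
- ``simulate_model2``: logistic-scale truth F = expit(A H) with
  orthonormal Gaussian factors.

``sample_genotypes`` then draws x_ij ~ Binomial(2, pi_ij).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .io import AlleleFreqMatrix, GenotypeMatrix


@dataclass
class AdmixtureModel:
    """PSD parameters: ancestral frequencies P (m x K), admixture
    proportions Q (K x n, columns on the simplex), concentration alpha."""

    P: np.ndarray
    Q: np.ndarray
    alpha: float
    K: int

    def __post_init__(self):
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("ancestral frequencies must lie in [0, 1]")
        if np.any(self.Q < 0) or np.any(self.Q > 1):
            raise ValueError("admixture proportions must lie in [0, 1]")
        if not np.allclose(self.Q.sum(axis=0), 1.0, atol=1e-10):
            raise ValueError("admixture columns must sum to 1")


@dataclass
class SimTruth:
    """A simulated truth: F plus the generating basis, when linear.

    For Model-1-style scenarios ``basis``/``loadings`` hold (S, Gamma)
    with F = loadings @ basis; for Model 2 they hold (H, A) with
    F = expit(loadings @ basis).
    """

    F: np.ndarray
    scenario: str
    seed: int
    basis: np.ndarray = None
    loadings: np.ndarray = None
    logistic: bool = False

    def __post_init__(self):
        if np.any(self.F < 0) or np.any(self.F > 1):
            raise ValueError("simulated frequencies must lie in [0, 1]")
        if self.basis is not None and self.loadings is not None:
            prod = self.loadings @ self.basis
            ref = expit(prod) if self.logistic else prod
            if not np.allclose(ref, self.F, atol=1e-12):
                raise ValueError("stored basis product is inconsistent with F")

    def freq_matrix(self) -> AlleleFreqMatrix:
        return AlleleFreqMatrix(self.F, provenance="simulated")


def _bn_population_freqs(rng, p_anc: np.ndarray, K: int, fst: float) -> np.ndarray:
    """Balding-Nichols Beta draws around ancestral frequencies, one column
    per population: Beta(p (1-fst)/fst, (1-p) (1-fst)/fst)."""
    scale = (1.0 - fst) / fst
    a = p_anc[:, None] * scale
    b = (1.0 - p_anc[:, None]) * scale
    return rng.beta(a, np.broadcast_to(b, (p_anc.size, K)))


def _even_labels(n: int, K: int) -> np.ndarray:
    """Individuals split as evenly as possible across K populations."""
    sizes = np.full(K, n // K)
    sizes[: n % K] += 1
    return np.repeat(np.arange(K), sizes)


def simulate_bn(m: int, n: int, K: int, fst: float, seed: int):
    """Discrete-population Balding-Nichols truth.

    Returns ``(SimTruth, labels)``; F has at most K distinct columns and
    the basis rows are the population indicator vectors.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    pop_freqs = _bn_population_freqs(rng, p_anc, K, fst)
    labels = _even_labels(n, K)
    F = pop_freqs[:, labels]
    basis = np.asarray(labels[None, :] == np.arange(K)[:, None], dtype=np.float64)
    truth = SimTruth(F=F, scenario=f"bn(K={K},fst={fst})", seed=seed,
                     basis=basis, loadings=pop_freqs)
    return truth, labels


def simulate_psd(m: int, n: int, K: int, alpha: float, fst: float, seed: int):
    """Admixture (PSD) truth F = P Q.

    P holds Balding-Nichols population frequencies, the columns of Q are
    Dirichlet(alpha, ..., alpha) draws.  Returns
    ``(SimTruth, AdmixtureModel)``; rank(F) <= K.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=m)
    P = _bn_population_freqs(rng, p_anc, K, fst)
    Q = rng.dirichlet(np.full(K, alpha), size=n).T
    F = P @ Q
    model = AdmixtureModel(P=P, Q=Q, alpha=alpha, K=K)
    truth = SimTruth(F=F, scenario=f"psd(K={K},alpha={alpha},fst={fst})", seed=seed,
                     basis=Q, loadings=P)
    return truth, model


def simulate_spatial(m: int, n: int, a: float, seed: int) -> SimTruth:
    """Rank-3 smooth spatial truth.

    Individuals sit at equally spaced positions t in [0, 1]; the basis
    rows are the orthogonalized (1, t, t^2).  Per-SNP loadings give a
    baseline frequency Uniform(0.15, 0.85) plus Gaussian positional
    effects scaled by ``a`` (smaller a = weaker, smoother structure); any
    row that would leave [0.05, 0.95] has its positional loadings shrunk
    back inside.  F is exactly rank 3 (d = 3).
    """
    if a <= 0:
        raise ValueError("a must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n)
    raw = np.vstack([t, t**2])
    # Gram-Schmidt against the intercept and each other, then unit-scale
    # to entry magnitude ~1 so loadings are on the frequency scale.
    basis_rows = []
    for row in raw:
        for prev in [np.ones(n)] + basis_rows:
            row = row - (row @ prev) / (prev @ prev) * prev
        basis_rows.append(row)
    basis = np.vstack([np.vstack(basis_rows) / np.abs(np.vstack(basis_rows)).max(axis=1, keepdims=True), np.ones(n)])

    baseline = rng.uniform(0.15, 0.85, size=m)
    coef = a * rng.normal(0.0, 1.0, size=(m, 2))
    spatial_part = coef @ basis[:2]
    lo, hi = 0.05, 0.95
    low_room = baseline - lo
    high_room = hi - baseline
    max_dev = np.abs(spatial_part).max(axis=1)
    room = np.minimum(low_room, high_room)
    shrink = np.where(max_dev > room, room / np.maximum(max_dev, 1e-300), 1.0)
    coef = coef * shrink[:, None]
    loadings = np.hstack([coef, baseline[:, None]])
    F = loadings @ basis
    return SimTruth(F=F, scenario=f"spatial(a={a})", seed=seed,
                    basis=basis, loadings=loadings)


def simulate_model2(m: int, n: int, d: int, seed: int, coef_scale: float = None) -> SimTruth:
    """Logistic-scale truth F = expit(A H).

    H stacks d-1 orthonormalized Gaussian rows on the ones row; the
    non-intercept columns of A are N(0, coef_scale^2) and the intercept
    column is logit of a Uniform(0.1, 0.9) baseline frequency, giving a
    realistic marginal allele-frequency spectrum.  ``coef_scale`` defaults
    to sqrt(n), which puts each factor's contribution to the logit at unit
    variance given the orthonormal (entry magnitude ~ 1/sqrt(n)) factor
    rows.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > n:
        raise ValueError("d must not exceed n")
    rng = np.random.default_rng(seed)
    if coef_scale is None:
        coef_scale = float(np.sqrt(n))
    if d == 1:
        H = np.ones((1, n))
    else:
        G = rng.standard_normal((n, d - 1))
        G -= G.mean(axis=0, keepdims=True)
        Qmat, _ = np.linalg.qr(G)
        H = np.vstack([Qmat.T, np.ones(n)])
    A = np.zeros((m, d))
    if d > 1:
        A[:, :-1] = rng.normal(0.0, coef_scale, size=(m, d - 1))
    A[:, -1] = logit(rng.uniform(0.1, 0.9, size=m))
    F = expit(A @ H)
    return SimTruth(F=F, scenario=f"model2(d={d},scale={coef_scale:g})", seed=seed,
                    basis=H, loadings=A, logistic=True)


def sample_genotypes(F, seed: int) -> GenotypeMatrix:
    """Draw x_ij ~ Binomial(2, pi_ij), independent across entries."""
    values = np.asarray(F.values if isinstance(F, AlleleFreqMatrix) else F, dtype=np.float64)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, values).astype(np.int8)
    return GenotypeMatrix(X)
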