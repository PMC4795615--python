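"""End-to-end simulation tables: basis-recovery accuracy and frequency
error for both estimators across the standard structure scenarios.

A single base seed expands into per-(scenario, stage) child seeds through
a fixed hashing scheme, so adding a scenario or stage never perturbs the
random streams of earlier ones.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .evaluate import freq_error, mean_r2_basis
from .lfa import LogisticFactorAnalysis, estimate_logistic_factors
from .pca import PCAAlleleFrequencies
from .simulate import (
    sample_genotypes,
    simulate_bn,
    simulate_psd,
    simulate_spatial,
)

#: Desk-scale defaults for the simulation tables.
DEFAULT_M = 10_000
DEFAULT_N = 500
DEFAULT_K = 3
DEFAULT_FST = 0.1


def child_seed(base: int, *keys) -> int:
    """Deterministic child seed < 2^31 from a base seed and string keys."""
    crcs = [zlib.crc32(str(k).encode()) for k in keys]
    ss = np.random.SeedSequence([int(base) & 0x7FFFFFFF, *crcs])
    return int(ss.generate_state(1)[0] % (2**31))


def _scenario_truth(name: str, m: int, n: int, K: int, fst: float, seed: int):
    if name == "bn":
        truth, _ = simulate_bn(m, n, K, fst, seed)
    elif name.startswith("psd"):
        alpha = float(name.split("=")[1])
        truth, _ = simulate_psd(m, n, K, alpha, fst, seed)
    elif name.startswith("spatial"):
        a = float(name.split("=")[1])
        truth = simulate_spatial(m, n, a, seed)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return truth


DEFAULT_SCENARIOS = (
    "bn",
    "psd:alpha=0.01",
    "psd:alpha=0.1",
    "psd:alpha=0.5",
    "psd:alpha=1",
    "spatial:a=0.1",
    "spatial:a=0.25",
    "spatial:a=0.5",
    "spatial:a=1",
)


def run_table1(
    scenarios=DEFAULT_SCENARIOS,
    m: int = DEFAULT_M,
    n: int = DEFAULT_N,
    K: int = DEFAULT_K,
    fst: float = DEFAULT_FST,
    d: int = None,
    seed: int = 0,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Basis-recovery accuracy per scenario.

    For each scenario: simulate F and genotypes, fit the PCA basis and the
    logistic factors at dimension d (default 3 = K), then report the mean
    R^2 of true F rows on S-tilde and of logit(F) rows on H-hat, averaged
    over ``n_reps`` replicate seeds.
    """
    d = d if d is not None else DEFAULT_K
    rows = []
    for name in scenarios:
        pca_r2s, lfa_r2s = [], []
        for rep in range(n_reps):
            truth = _scenario_truth(name, m, n, K, fst, child_seed(seed, name, "sim", rep))
            X = sample_genotypes(truth.F, child_seed(seed, name, "geno", rep)).as_float()
            pca = PCAAlleleFrequencies(n_components=d).fit(X)
            pca_r2s.append(mean_r2_basis(truth.F, pca.basis_, scale="freq").mean_r2)
            factors = estimate_logistic_factors(X, d)
            lfa_r2s.append(mean_r2_basis(truth.F, factors.H, scale="logit").mean_r2)
        rows.append(
            {
                "scenario": name,
                "pca_mean_r2": float(np.mean(pca_r2s)),
                "lfa_mean_r2": float(np.mean(lfa_r2s)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def run_table2(
    alphas=(0.01, 0.1, 0.5, 1.0),
    m: int = DEFAULT_M,
    n: int = DEFAULT_N,
    K: int = DEFAULT_K,
    fst: float = DEFAULT_FST,
    d: int = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency-estimation error under the PSD model for varying alpha.

    Reports RMSE, MAE and Binomial KL divergence of the PCA estimate
    F-tilde and the LFA estimate F-hat against the simulated truth.
    """
    d = d if d is not None else DEFAULT_K
    rows = []
    for alpha in alphas:
        name = f"psd:alpha={alpha}"
        truth, _ = simulate_psd(m, n, K, alpha, fst, child_seed(seed, name, "sim", 0))
        X = sample_genotypes(truth.F, child_seed(seed, name, "geno", 0)).as_float()
        pca = PCAAlleleFrequencies(n_components=d).fit(X)
        lfa = LogisticFactorAnalysis(n_components=d).fit(X)
        pca_err = freq_error(truth.F, pca.F_)
        lfa_err = freq_error(truth.F, lfa.F_)
        rows.append(
            {
                "alpha": alpha,
                "pca_rmse": pca_err.rmse,
                "pca_mae": pca_err.mae,
                "pca_kl": pca_err.kl,
                "lfa_rmse": lfa_err.rmse,
                "lfa_mae": lfa_err.mae,
                "lfa_kl": lfa_err.kl,
                "pca_any_outside": bool(
                    np.any((pca.F_star_ < 0) | (pca.F_star_ > 1))
                ),
            }
        )
    return pd.DataFrame(rows)
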