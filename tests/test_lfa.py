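"""Logistic factor analysis: factor estimation and per-SNP Binomial GLM."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from lfapy import (
    LogisticFactorAnalysis,
    estimate_logistic_factors,
    fit_snp_logistic,
    lfa_allele_freq,
    sample_genotypes,
    simulate_model2,
    simulate_psd,
)
from lfapy.lfa import binomial_logistic_mle, select_row_subset


def generic_mle(x, H):
    """Independent numerical MLE via Nelder-Mead/BFGS on the likelihood."""

    def negll(a):
        eta = a @ H
        return -(x * eta - 2 * np.logaddexp(0, eta)).sum()

    res = minimize(negll, np.zeros(H.shape[0]), method="BFGS", tol=1e-12)
    return res.x


def smallest_canonical_correlation(A, B):
    """Smallest canonical correlation between the row spaces of A and B."""
    Qa, _ = np.linalg.qr(A.T)
    Qb, _ = np.linalg.qr(B.T)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return s.min()


class TestFactors:
    def test_d1_is_ones_row(self, rng):
        X = rng.integers(0, 3, (30, 12)).astype(float)
        fac = estimate_logistic_factors(X, 1)
        np.testing.assert_array_equal(fac.H, np.ones((1, 12)))

    def test_construction_contract(self, rng):
        X = rng.integers(0, 3, (200, 40)).astype(float)
        fac = estimate_logistic_factors(X, 4)
        np.testing.assert_allclose(fac.H[-1], 1.0)
        gram = fac.H[:-1] @ fac.H[:-1].T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_subspace_recovery_model2(self):
        truth = simulate_model2(5000, 200, 3, seed=31)
        X = sample_genotypes(truth.F, seed=32)
        fac = estimate_logistic_factors(X, 3)
        assert smallest_canonical_correlation(fac.H, truth.basis) >= 0.99

    def test_row_subset_fallback(self, rng):
        # Frequencies hugging the boundary force the margin-ranked fallback.
        F_star = rng.uniform(0.0005, 0.9995, size=(300, 40))
        subset = select_row_subset(F_star, C=0.4, d=3)
        assert subset.fallback
        assert len(subset) >= 10

    def test_too_few_usable_rows(self, rng):
        F_star = np.full((5, 10), 0.5) + rng.normal(0, 0.01, (5, 10))
        with pytest.raises(ValueError, match="usable rows"):
            select_row_subset(np.clip(F_star, -0.2, 0.5), C=0.01, d=4)


class TestSnpLogistic:
    def test_intercept_only_mle_is_logit_freq(self):
        H = np.ones((1, 4))
        fit = fit_snp_logistic(np.array([1.0, 1, 1, 1]), H)
        np.testing.assert_allclose(fit.coef, [0.0], atol=1e-8)
        fit2 = fit_snp_logistic(np.array([2.0, 2, 1, 1, 0, 0]), np.ones((1, 6)))
        np.testing.assert_allclose(fit2.coef, [0.0], atol=1e-8)

    def test_d2_toy_matches_generic_optimizer(self):
        H = np.vstack([np.array([-1.0, -1, 0, 0, 1, 1]), np.ones(6)])
        x = np.array([0.0, 1, 1, 1, 1, 2])
        fit = fit_snp_logistic(x, H)
        ref = generic_mle(x, H)
        np.testing.assert_allclose(fit.coef, ref, atol=1e-6)

    def test_perfect_separation_flagged_and_capped(self):
        fit = fit_snp_logistic(np.zeros(4), np.ones((1, 4)), coef_cap=30.0)
        assert fit.separated
        assert np.all(np.abs(fit.coef) <= 30.0)

    def test_statsmodels_glm_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(100):
            n = int(rng.integers(30, 60))
            d = int(rng.integers(2, 4))
            H = np.vstack([rng.standard_normal((d - 1, n)), np.ones(n)])
            a_true = rng.normal(0, 0.8, d)
            x = rng.binomial(2, expit(a_true @ H)).astype(float)
            if x.min() == x.max():
                continue
            fit = fit_snp_logistic(x, H)
            if fit.separated:
                continue
            glm = sm.GLM(
                np.column_stack([x, 2 - x]), H.T, family=sm.families.Binomial()
            ).fit(tol=1e-12)
            np.testing.assert_allclose(fit.coef, glm.params, atol=1e-5)

    def test_missing_dropped_from_likelihood(self, rng):
        n = 40
        H = np.vstack([rng.standard_normal(n), np.ones(n)])
        x = rng.binomial(2, 0.4, n).astype(float)
        x_miss = x.copy()
        x_miss[[3, 17, 29]] = np.nan
        keep = np.isfinite(x_miss)
        fit_full = fit_snp_logistic(x_miss, H)
        fit_sub = fit_snp_logistic(x[keep], H[:, keep])
        np.testing.assert_allclose(fit_full.coef, fit_sub.coef, atol=1e-8)

    def test_too_few_observations(self):
        H = np.vstack([np.arange(3.0), np.ones(3)])
        with pytest.raises(ValueError, match="fewer"):
            fit_snp_logistic(np.array([1.0, np.nan, np.nan]), H)


class TestLfaFit:
    def test_d1_frequencies_are_half_row_means(self, rng):
        X = rng.integers(0, 3, (20, 15)).astype(float)
        X[0] = 1  # keep rows polymorphic enough to avoid separation
        fit = lfa_allele_freq(X, d=1)
        expected = X.mean(axis=1) / 2.0
        sel = ~fit.separation_flag
        np.testing.assert_allclose(
            fit.F_hat.values[sel], np.tile(expected[sel, None], (1, 15)), atol=1e-8
        )

    def test_allele_flip_symmetry(self, rng):
        X = rng.integers(0, 3, (150, 30)).astype(float)
        f = lfa_allele_freq(X, d=3)
        g = lfa_allele_freq(2.0 - X, d=3)
        np.testing.assert_allclose(g.F_hat.values, 1.0 - f.F_hat.values, atol=1e-6)

    def test_frequencies_strictly_inside_unit_interval(self, rng):
        X = rng.integers(0, 3, (100, 25)).astype(float)
        X[0] = 0.0  # monomorphic row must still map strictly inside (0,1)
        fit = lfa_allele_freq(X, d=2)
        assert fit.F_hat.values.min() > 0.0
        assert fit.F_hat.values.max() < 1.0

    def test_score_equations(self, rng):
        X = rng.integers(0, 3, (120, 40)).astype(float)
        fit = lfa_allele_freq(X, d=3)
        ok = fit.converged & ~fit.separation_flag
        assert ok.mean() > 0.9
        resid = (X - 2.0 * fit.F_hat.values) @ fit.H.H.T
        assert np.abs(resid[ok]).max() < 1e-6

    def test_residual_deviance_nonincreasing_in_d(self, rng):
        truth = simulate_model2(300, 60, 3, seed=5)
        X = sample_genotypes(truth.F, seed=6).as_float()
        from lfapy.lfa import _saturated_loglik

        sat = np.array([_saturated_loglik(X[i]) for i in range(300)])
        mean_dev = []
        for d in (1, 2, 3, 4):
            fit = LogisticFactorAnalysis(n_components=d).fit(X)
            mean_dev.append(np.mean(2 * (sat - fit.loglik_)))
        assert np.all(np.diff(mean_dev) <= 1e-8)

    def test_psd_table_regime_logit_r2(self):
        from lfapy import mean_r2_basis

        truth, _ = simulate_psd(10_000, 500, 3, 0.1, 0.1, seed=41)
        X = sample_genotypes(truth.F, seed=42)
        fac = estimate_logistic_factors(X, 3)
        score = mean_r2_basis(truth.F, fac.H, scale="logit")
        assert score.mean_r2 >= 0.98

    def test_vectorized_matches_single_snp(self, rng):
        n = 30
        H = np.vstack([rng.standard_normal((2, n)), np.ones(n)])
        X = rng.binomial(2, 0.5, (10, n)).astype(float)
        A, ll, conv, sep = binomial_logistic_mle(X, H)
        for i in range(10):
            single = fit_snp_logistic(X[i], H)
            np.testing.assert_allclose(single.coef, A[i], atol=1e-8)
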