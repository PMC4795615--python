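"""Structure statistics: deviance ranking, conditional HWE, structural FST,
dimension selection."""

import numpy as np
import pytest

from lfapy import (
    GenotypeMatrix,
    estimate_logistic_factors,
    hwe_gof,
    rank_snps,
    sample_genotypes,
    select_dimension,
    simulate_bn,
    simulate_model2,
    snp_deviance,
    structural_fst,
)
from lfapy.lfa import LogisticFactors


def make_factors(H):
    H = np.asarray(H, dtype=float)
    return LogisticFactors(H=H, d=H.shape[0], subset_size=0, C=0.01)


class TestDeviance:
    def test_d1_deviance_zero(self, rng):
        x = rng.integers(0, 3, 20).astype(float)
        res = snp_deviance(x, make_factors(np.ones((1, 20))))
        assert res.deviance == 0.0 and res.df == 0

    def test_two_population_toy(self):
        # pop 1 all genotype 0, pop 2 all genotype 2; the factor is the
        # population indicator -> perfect separation, deviance equals twice
        # the intercept-only log-likelihood deficit -2n*2*log(1/2) up to the
        # coefficient cap.
        n = 20
        indicator = np.repeat([-1.0, 1.0], n // 2)
        H = make_factors(np.vstack([indicator, np.ones(n)]))
        x = np.repeat([0.0, 2.0], n // 2)
        res = snp_deviance(x, H)
        # intercept-only loglik: p=1/2 -> 2n log(1/2); full fit approaches 0
        # (coefficients diverge toward the cap under perfect separation)
        expected_max = 2.0 * (0.0 - 2 * n * np.log(0.5))
        assert 0.99 * expected_max < res.deviance <= expected_max + 1e-9
        # must exceed any null SNP's deviance by a wide margin
        null_x = np.random.default_rng(0).binomial(2, 0.5, n).astype(float)
        assert res.deviance > snp_deviance(null_x, H).deviance + 10

    def test_flip_invariance(self, rng):
        n = 30
        H = make_factors(np.vstack([rng.standard_normal(n), np.ones(n)]))
        x = rng.binomial(2, 0.4, n).astype(float)
        a = snp_deviance(x, H).deviance
        b = snp_deviance(2.0 - x, H).deviance
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestRanking:
    def test_planted_outlier_ranks_first(self):
        rng = np.random.default_rng(3)
        n = 100
        labels = np.repeat([0, 1], n // 2)
        F = np.full((1000, n), 0.5)
        F[0] = np.where(labels == 0, 0.05, 0.95)
        X = sample_genotypes(F, seed=4)
        H = make_factors(
            np.vstack([(labels - 0.5) / np.sqrt(n / 4), np.ones(n)])
        )
        results = rank_snps(X, H)
        assert results[0].snp_id == "snp_0"
        assert results[0].rank == 1

    def test_tie_break_deterministic(self):
        X = GenotypeMatrix(
            np.tile([0, 1, 2, 1, 0, 1], (4, 1)), snp_ids=["d", "b", "a", "c"]
        )
        H = make_factors(np.ones((1, 6)))
        results = rank_snps(X, H)
        assert [r.rank for r in results] == [1, 2, 3, 4]
        assert [r.snp_id for r in results] == ["a", "b", "c", "d"]

    def test_d1_all_zero(self, rng):
        X = rng.integers(0, 3, (5, 10))
        results = rank_snps(GenotypeMatrix(X), make_factors(np.ones((1, 10))))
        assert all(r.deviance == 0.0 for r in results)
        assert sorted(r.snp_id for r in results) == sorted(f"snp_{i}" for i in range(5))


class TestHweGof:
    def test_perfect_fit(self):
        res = hwe_gof(np.array([0.0, 1, 1, 2]), np.full(4, 0.5))
        np.testing.assert_allclose(res.expected_counts, [1, 2, 1])
        np.testing.assert_array_equal(res.observed_counts, [1, 2, 1])
        assert res.statistic == 0.0

    def test_worked_example_all_zero(self):
        res = hwe_gof(np.zeros(4), np.full(4, 0.5))
        np.testing.assert_allclose(res.expected_counts, [1, 2, 1])
        np.testing.assert_array_equal(res.observed_counts, [4, 0, 0])
        assert res.statistic == pytest.approx(12.0)

    def test_flip_invariance(self, rng):
        x = rng.binomial(2, 0.3, 50).astype(float)
        pi = rng.uniform(0.2, 0.4, 50)
        a = hwe_gof(x, pi).statistic
        b = hwe_gof(2.0 - x, 1.0 - pi).statistic
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_counts_sum_to_nonmissing(self, rng):
        x = rng.binomial(2, 0.5, 30).astype(float)
        x[:4] = np.nan
        res = hwe_gof(x, rng.uniform(0.3, 0.7, 30))
        assert res.observed_counts.sum() == 26
        assert res.expected_counts.sum() == pytest.approx(26, abs=1e-8)

    def test_null_calibration_below_chi2_tail(self, rng):
        # genotypes drawn from their own heterogeneous pi: the statistic's
        # 5% exceedance of the chi2(2) critical value stays near nominal
        from scipy.stats import chi2

        m, n = 1000, 80
        stats = []
        for i in range(m):
            pi = rng.uniform(0.2, 0.8, n)
            x = rng.binomial(2, pi).astype(float)
            stats.append(hwe_gof(x, pi).statistic)
        frac = np.mean(np.array(stats) > chi2.ppf(0.95, df=2))
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / m)


class TestStructuralFst:
    def test_constant_is_zero(self):
        assert structural_fst(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-15)

    def test_full_fixation_is_one(self):
        assert structural_fst(np.array([0.0, 0, 1, 1])) == pytest.approx(1.0)

    def test_bounds(self, rng):
        for _ in range(50):
            pi = rng.random(rng.integers(2, 30))
            assert 0.0 <= structural_fst(pi) <= 1.0

    def test_bn_finite_k_expectation(self):
        # Analytic oracle: with K populations the population-variance measure
        # has expectation ~ fst (1 - 1/K) / (1 - fst/K).
        fst, K = 0.1, 2
        truth, _ = simulate_bn(5000, 100, K, fst, seed=9)
        mean_fst = np.mean([structural_fst(truth.F[i]) for i in range(truth.F.shape[0])])
        expected = fst * (1 - 1 / K) / (1 - fst / K)
        assert mean_fst == pytest.approx(expected, rel=0.10)


class TestSelectDimension:
    def test_single_candidate(self, rng):
        X = rng.integers(0, 3, (60, 25)).astype(float)
        d_best, scores = select_dimension(X, [4])
        assert d_best == 4
        assert list(scores["d"]) == [4]

    def test_moderate_model2_recovery(self):
        truth = simulate_model2(1500, 150, 2, seed=77)
        X = sample_genotypes(truth.F, seed=78)
        d_best, scores = select_dimension(X, [1, 2, 3])
        assert d_best == 2
        assert set(scores.columns) >= {"d", "mean_deviance", "bic", "mean_hwe_stat"}

    def test_unstructured_picks_one(self, rng):
        p = rng.uniform(0.2, 0.8, 800)
        X = rng.binomial(2, np.tile(p[:, None], (1, 100))).astype(float)
        d_best, _ = select_dimension(X, [1, 2, 3])
        assert d_best == 1

    def test_candidate_contract(self, rng):
        X = rng.integers(0, 3, (20, 10)).astype(float)
        with pytest.raises(ValueError):
            select_dimension(X, [])
        with pytest.raises(ValueError):
            select_dimension(X, [0, 2])
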