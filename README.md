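# lfapy

Estimation of **individual-specific allele frequencies** from biallelic SNP
genotype matrices in structured populations, by two latent-variable models:

- **Model 1 (PCA)** — the m×n frequency matrix is a linear basis expansion,
  F = ΓS, with Γ (m×d) real loadings and S (d×n) a real basis whose last
  row is 1. It is estimated by projecting the row-centered genotype matrix
  X onto its top d−1 principal components, rescaling by 1/2, and truncating
  into [C, 1−C] with C = 1/(2n) by default.
- **Model 2 (logistic factor analysis, LFA)** — the *logit* of the
  frequencies is the linear object: logit π_ij = Σ_k a_ik h_kj, i.e.
  L = AH with "logistic factors" H (last row the intercept 1). H is
  estimated from the right singular vectors of the standardized logit of
  the stably-estimated PCA rows; A is then obtained per SNP by
  Binomial(2, π) logistic regression of genotypes x_ij ∈ {0,1,2} on the
  rows of Ĥ, so that F̂ = logit⁻¹(ÂĤ) lies strictly inside (0,1).

On top of the estimators the package provides: deviance-based ranking of
SNPs by how differentiated they are with respect to structure (full
logistic fit vs. intercept-only), a goodness-of-fit test of Hardy–Weinberg
equilibrium *conditional on structure* (genotype classes against
(1−π)², 2π(1−π), π²), a structural F_ST analogue
Var_j(π_ij)/(π̄(1−π̄)), BIC-based selection of the latent dimension d,
simulators for Balding–Nichols, admixture (PSD), spatial and
logistic-factor truth, and the accuracy metrics (mean R² basis recovery;
RMSE/MAE/Binomial-KL frequency error) used to validate them.

Intended users: population and statistical geneticists who need
well-behaved per-individual allele-frequency estimates for downstream
inference (structure-aware HWE tests, differentiation scans,
association-test corrections) without committing to a parametric admixture
model.

## Worked example

```python
import lfapy as L

# admixed truth: 3 ancestral populations, Dirichlet(0.1) admixture
truth, model = L.simulate_psd(m=2000, n=200, K=3, alpha=0.1, fst=0.1, seed=1)
X = L.sample_genotypes(truth.F, seed=2)

fit = L.lfa_allele_freq(X, d=3)            # logistic factor analysis
pca = L.pca_allele_freq(X, d=3)            # PCA-based estimate

print(L.mean_r2_basis(truth.F, fit.H.H, scale="logit").mean_r2)
print(L.freq_error(truth.F, fit.F_hat).rmse)
print(L.freq_error(truth.F, pca.F_tilde).rmse)
```

prints

```
0.9802641732466761
0.0405890579900944
0.03921145144550781
```

— the logistic factors explain ≈98.0% of the variance of the true
logit-frequency rows, and both estimators recover the 400 000 individual
frequencies to ≈0.04 RMSE at this reduced scale (errors shrink further at
larger m, n). The same analyses are available as estimator classes
(`LogisticFactorAnalysis`, `PCAAlleleFrequencies` with sklearn-style
`fit`/`fit_transform` and trailing-underscore attributes) and from the
command line:

```sh
lfapy simulate --scenario psd --m 2000 --n 200 --seed 1 --out-prefix sim
lfapy lfa --matrix sim.geno.tsv --d 3 --out freqs.tsv --save-factors H.tsv
lfapy rank --matrix sim.geno.tsv --d 3 --out ranks.tsv
lfapy select-d --matrix sim.geno.tsv --dmin 1 --dmax 5 --out dscores.tsv
```

PLINK 1 binary triplets are accepted anywhere a genotype matrix is
(`--bed data.bed`).

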