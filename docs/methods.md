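# Methods

## Data model

Genotypes are biallelic SNP calls x_ij ∈ {0, 1, 2}, the count of the
designated (counted) allele for SNP i in individual j, arranged as an
m×n matrix X (SNPs × individuals — the natural orientation when every
row gets its own model fit). Each entry is modeled as
x_ij ~ Binomial(2, π_ij), where π_ij is the *individual-specific allele
frequency*: in a structured population the success probability is allowed
to differ across individuals because their (latent) ancestry differs. The
object of estimation is the full m×n matrix F = (π_ij).

Missing calls are carried through the data model as an explicit sentinel
(−1 in integer matrices, NaN on the numeric path) rather than imputed at
I/O time: the PCA path mean-imputes them only inside its linear algebra
(a centered value of 0), and the logistic fits drop them from the
likelihood, which factorizes over individuals. All estimators satisfy the
allele-flip symmetry estimate(2−X) = 1−estimate(X), so the choice of
counted allele is inconsequential.

## Model 1: PCA estimate

F = ΓS with unrestricted real Γ (m×d) and S (d×n); the last row of S is
constrained to 1 so that d = 1 means "no structure" and row i of F
collapses to the marginal frequency μ_i/2. Estimation: center each row of
X by its mean μ̃_i (missing → 0 after centering); take the top d−1
singular triplets of the centered matrix; the projection plus μ̃_i, times
1/2, is the pre-truncation estimate F̃* = Γ̃S̃ (Γ̃'s last column is μ̃/2,
S̃'s last row is 1). Because nothing constrains a projection to [0,1],
F̃* is finally clamped into [C, 1−C].

- **C (truncation constant)**, default 1/(2n): the smallest frequency
  distinguishable from 0 when 2n alleles are observed. Recorded in the
  fit object for reproducibility.
- Monomorphic rows are retained (their centered row is 0 and the estimate
  is the clamped μ̃_i/2); any minor-allele-frequency filtering is an
  explicit, separate step (`--min-maf`), never silent.
- The numeric path accepts fractional "genotypes" on purpose: a noiseless
  harness can feed 2F directly and must recover an exactly low-rank F to
  machine precision; the CLI enforces integer coding.

## Model 2: logistic factor analysis

The logit of the frequencies is modeled linearly: L = logit(F) = AH, all
entries real, H (d×n) with ones as the last row (intercept). Estimation
is two-stage:

1. **Factors.** Run the Model-1 projection at the same d. Keep the rows
   of F̃* whose entries all lie strictly inside (C, 1−C) — rows where the
   logit is numerically stable; logit that submatrix, center and
   standard-deviation-scale each row (sample SD, n−1), and take the top
   d−1 right singular vectors, stacked on the ones row, as Ĥ. The subset
   only needs to span the row space of L, not be exhaustive. If fewer
   than max(d, 10) rows fully qualify, rows are ranked by their margin
   min_j min(π̃*_ij, 1−π̃*_ij) and the top max(10d, 100) rows with
   positive margin are used instead (rows with zero logit variance are
   excluded either way — they carry no structure signal).
2. **Coefficients.** Each SNP is fitted by Binomial(2, ·) logistic
   regression of x_i on the rows of Ĥ — Newton/IRLS with step-halving,
   vectorized across all SNPs (the per-SNP d×d systems are solved as a
   stacked batch). Convergence when the log-likelihood improves by less
   than 1e-10 (quadratic convergence makes the final score-equation
   residuals ≲1e-8 in practice), capped at 100 iterations.

Then L̂ = ÂĤ and F̂ = expit(L̂) ∈ (0,1) strictly — the advantage over
the PCA estimate, whose pre-truncation values routinely leave [0,1]
(observed in every desk-scale admixture simulation here).

- **Separation cap**: if any coefficient exceeds ±30 during iteration
  (monomorphic SNPs, or SNPs perfectly aligned with structure), the SNP
  is flagged and its coefficients are clipped to ±30. logit⁻¹(30) is
  within ~1e-13 of the boundary, so this is numerically equivalent to
  fixation while keeping every downstream quantity finite.
- The starting point is the intercept-only MLE logit(x̄_i/2), which makes
  d = 1 exact in a single step.

## SNP differentiation by deviance

A SNP differentiated with respect to structure is one whose genotypes are
explained far better by the structured logistic model than by the
intercept-only model: deviance = 2[ℓ(full) − ℓ(intercept-only)], with
d − 1 degrees of freedom (0 at d = 1 by construction). The intercept-only
log-likelihood has the closed form S log p̂ + (2n−S) log(1−p̂). Ranking
is by descending deviance with lexicographic snp_id tie-breaks, so equal
inputs always produce identical output. Capped (separated) fits keep
their ranking position and are flagged. For unstructured SNPs evaluated
against factors *estimated from independent data*, the deviance is
χ²_{d−1}-calibrated; note that evaluating SNPs against factors estimated
from the very same matrix inflates the null mean by roughly the
Marchenko–Pastur edge factor (1+√(n/m))² — the factors are the directions
of maximal spurious alignment — so calibration statements here always use
held-out factors. No MAF adjustment is applied to the ranking; MAF is
reported alongside so users can stratify (deviance tends to be larger for
common SNPs).

## Hardy–Weinberg equilibrium conditional on structure

Given fitted frequencies, genotype class g ∈ {0,1,2} for individual j has
probability (1−π̂_ij)², 2π̂_ij(1−π̂_ij), π̂_ij². The test compares
observed class counts with expected counts summed over individuals via a
Pearson statistic; an empty expected class with observed members yields
+inf (flagged rather than propagating a division by zero). The statistic
is invariant under simultaneous genotype flip and π → 1−π.

## Structural F_ST

For one SNP, F_ST = Var_j(π_ij) / (π̄(1−π̄)) with the population (1/n)
variance, 0 at fixation of the mean. This lies in [0,1] and reaches 1
only when all frequencies are 0 or 1 with both present. With K discrete
subpopulations of Balding–Nichols spread fst, its expectation is
approximately fst·(1−1/K)/(1−fst/K): the measure sees the realized
between-group variance, so with few groups it is biased low by the
factor (1−1/K) (exactly the population-variance correction); it recovers
the generating fst well when K is moderately large.

## Dimension selection

The latent dimension is chosen by penalized goodness of fit: for each
candidate d, fit LFA and score it by the mean per-SNP residual deviance
plus d·log(n) — a per-SNP BIC, since each SNP's regression spends d
parameters on n observations. Raw (unpenalized) fit statistics are
monotone in d — an extra factor always absorbs some noise, by about
(1+√(n/m))² deviance units per dimension in-sample — so a raw minimum
would always pick the largest candidate; the log(n) penalty dominates
that spurious gain by a wide margin while true structure dimensions
reduce the deviance by tens of units, making the minimum sharp at the
generating d. (A parametric-bootstrap calibration of the conditional-HWE
statistic was evaluated as an alternative and rejected: the factor
pipeline is nearly a fixed point of its own fitted F̂, so bootstrap nulls
sit systematically below the observed statistic even at the true d.) The
mean conditional-HWE statistic per candidate is reported alongside as a
diagnostic. Ties go to the smallest d.

## Simulators

All simulators are pure functions of their seed and return the truth F
(with its generating basis where one exists) so estimates can be scored
against it.

- **Balding–Nichols (bn)**: ancestral frequencies p_i ~ Uniform(0.1, 0.9);
  subpopulation k's frequency ~ Beta(p(1−fst)/fst, (1−p)(1−fst)/fst)
  (mean p, variance fst·p(1−p)); individuals split evenly over K groups.
- **Admixture (psd)**: F = PQ with P as above and Q columns
  ~ Dirichlet(α,…,α); α = 0.01 is near-discrete, α = 1 heavily admixed.
- **Spatial**: individuals at equally spaced positions t ∈ [0,1]; basis
  rows are the orthogonalized (1, t, t²) scaled to unit entry magnitude;
  per-SNP loadings are a Uniform(0.15, 0.85) baseline plus positional
  coefficients a·N(0,1), shrunk per row so F stays inside [0.05, 0.95];
  F is exactly rank 3. This is this package's own smooth rank-3
  construction for continuously structured populations.
- **Logistic-scale truth (model2)**: H stacks d−1 orthonormalized,
  centered Gaussian rows on the intercept row; non-intercept coefficients
  are N(0, coef_scale²) with coef_scale defaulting to √n so each factor
  contributes unit variance on the logit scale (orthonormal rows have
  entries ~1/√n); the intercept column is logit(Uniform(0.1, 0.9)),
  giving a realistic marginal frequency spectrum.

Default desk-scale dimensions are m = 10 000 SNPs × n = 500 individuals
with K = 3 and fst = 0.1 — large enough that basis recovery is nearly
exact yet the full scenario sweep runs in minutes on one CPU. Since the
basis-recovery R² deficit empirically shrinks ∝ 1/m, results at larger m
only improve on the desk-scale numbers. What these simulations do *not*
emulate: linkage disequilibrium (entries are independent given F),
genotyping error, relatedness between individuals, or ascertainment of
SNPs — so passing tests demonstrate correctness of the estimators under
the stated models, not robustness to those real-data features.

## Metrics

- **Basis recovery**: regress each true frequency row (or its logit) on
  the estimated basis rows by OLS (the basis's ones row is the intercept;
  one is appended if absent) and average R² = 1 − RSS/TSS across SNPs.
  Constant rows (TSS = 0) count as R² = 1 — there is no structure to
  recover. The score is invariant to invertible re-parameterization of
  the basis, which is why basis recovery is the right yardstick for
  estimators identified only up to rotation.
- **Frequency error**: entrywise RMSE and MAE, plus the mean
  Kullback–Leibler divergence between Binomial(2, π) and Binomial(2, π̂),
  2[π log(π/π̂) + (1−π) log((1−π)/(1−π̂))], 0·log 0 = 0, natural log.

## Numerical choices

- Truncated SVD: dense LAPACK below min(m,n) = 500, Lanczos (ARPACK
  `svds`) above, with a seeded starting vector and tolerance 1e-10;
  correctness is defined by agreement with the dense decomposition. Sign
  ambiguity is resolved by making each right singular vector's
  largest-magnitude entry positive, so outputs are bit-reproducible.
- A single pipeline seed expands into per-(scenario, stage, replicate)
  child seeds by hashing the stage labels into a seed sequence, so adding
  a stage never perturbs earlier streams; all derived seeds stay below
  2³¹.
- PLINK 1 binary I/O (SNP-major, 2-bit codes) is implemented directly and
  cross-checked in the tests against an independent byte-level decoder.

## Known limitations

- The factor estimate feeds on the PCA pre-truncation matrix; under
  extremely strong boundary concentration (most rows truncated) the
  stable-row subset shrinks and the margin-ranked fallback engages, which
  is an approximation with no optimality guarantee.
- Estimated factors are identified only up to invertible linear
  transformation; admixture proportions are deliberately *not* derived
  from them (transforming the basis back onto the simplex is not
  implemented).
- The HWE statistic is compared to no reference distribution internally;
  its null distribution under heterogeneous π̂ is not exactly χ², and
  significance assessment (e.g. permutation-based) is out of scope.
- VCF input, multi-allelic sites, phased haplotypes and dosages are not
  supported; genotypes enter as hard {0,1,2} calls.
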