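# Methods

## The twin model

For two traits observed on both members of a twin pair, the observation
vector is y = (trait1_t1, trait2_t1, trait1_t2, trait2_t2). Each variance
component — additive genetic (A), shared environment (C) and unique
environment (E) — has a 2×2 cross-trait covariance block parameterised as
Σ_X = L_X L_Xᵀ with L_X lower-triangular and non-negative diagonal, which
makes every implied covariance positive semi-definite by construction and
lets AE/CE submodels arise as boundary solutions rather than separate
model fits. The implied 4×4 covariance is

    Σ_zyg = [[Σ_A + Σ_C + Σ_E,  k_A Σ_A + k_C Σ_C],
             [k_A Σ_A + k_C Σ_C, Σ_A + Σ_C + Σ_E]]

with (k_A, k_C) = (1, 1) for MZ pairs and (½, 1) for DZ pairs. An ADE
variant replaces C by a dominance component with DZ coefficients (½, ¼);
C and D are never estimated together.

**Likelihood.** Full-information maximum likelihood: each pair contributes
the multivariate-normal density of its *observed* sub-vector, so pairs with
a missing co-twin or single missing trait value are retained at reduced
dimension rather than dropped. Two free means (per trait, shared across
twins and zygosity groups) absorb imperfect standardisation of the input
residuals. Internally pairs are grouped by (zygosity, missingness pattern)
into sufficient statistics — count, mean, scatter — so one likelihood
evaluation costs O(patterns), independent of the number of pairs; the test
suite verifies this grouped form against direct per-pair density evaluation
to 1e-8.

**Optimisation.** L-BFGS-B over the nine Cholesky paths and two means,
diagonals bounded at zero (E diagonals at 1e-4 to keep the likelihood
finite), from five starting points: a Falconer-style moment start (A from
2·(MZ−DZ) cross-twin covariance contrast, C from 2·DZ−MZ, E from the
remainder, each projected to the nearest PSD matrix) plus four fixed
variance splits. The best optimum is kept, ties broken by parameter norm.
Near-zero fitted component variances are flagged as boundary solutions.

**Reporting.** The Cholesky optimum is transformed to the
correlated-factors solution: standardised proportions A_i, C_i, E_i (which
sum to 1 per trait) and factor correlations r_A, r_C, r_E (reported as
missing when a component variance is zero, since the correlation is then
undefined). The phenotypic correlation decomposes exactly as
r_P = √(A₁A₂) r_A + √(C₁C₂) r_C + √(E₁E₂) r_E; the genetic term
√A₁·r_A·√A₂ is the shared genetic effect and its ratio to r_P the genetic
proportion of the correlation.

**Confidence intervals.** Default is profile likelihood at the 95% level:
a bound on a derived quantity q is the value of q at which the constrained
−2 lnL rises by the χ²(1) 0.95-quantile (3.84). The constrained optimum is
computed by quadratic penalty with escalating weight (constraint satisfied
to 1e-3), the bound bracketed by doubling steps and located by bisection;
endpoints pinned at the parameter-space edge (0/1 for proportions, ±1 for
correlations) are flagged `boundary`. A parametric bootstrap (refit of
cohorts resampled from the fitted model, percentile interval) is available
as a cross-check; the suite requires the two methods to agree to the first
decimal on heritability. CI calibration is tested as likelihood-ratio
coverage: over 500 replicate simulations, the profile interval covers the
generating heritability 95% ± 3% of the time (equivalent to, and far
cheaper than, locating both endpoints per replicate).

## Generator calibration

The published bivariate fit reports the per-trait proportions and r_A but
not r_C or r_E. The generator fixes r_C = 0 — the shared-environment
variance of refractive error is 0.5%, so the √(C₁C₂) r_C term is bounded by
~0.025 in magnitude and its omission is numerically negligible — and solves
r_E from the one-unknown linear identity so the implied r_P equals −0.116
exactly (giving r_E = −0.106). Published trait-1 proportions
(0.85/0.005/0.15) sum to 1.005 after rounding and are renormalised before
simulation (A₁ = 0.8458). Infeasible targets (|r_E| > 1) raise a
calibration error rather than clipping.

Twin pairs are drawn as sums of component deviates: MZ co-twins share one
bivariate A draw and one C draw; DZ co-twins share the C draw plus a common
A part, with an independent twin-specific A part, each carrying half of
Σ_A — this reproduces the required first and second moments exactly without
a kinship matrix. E is independent per twin. Per-trait variances are 1 by
construction.

## Genotype and GWAS simulation

Haplotypes are latent Gaussian AR(1) series per LD block (lag-one
correlation `within_block_r`), thresholded at each SNP's allele-frequency
quantile; the dosage is the sum of two independent haplotypes. Blocks are
1 Mb apart (outside any clumping window) with SNPs 2 kb apart inside a
block. Thresholding attenuates the binary-scale correlation relative to the
latent one (tetrachoric attenuation), so `within_block_r = 0.8` yields
adjacent-SNP dosage r² around 0.25–0.35 rather than 0.64; the qualitative
contrast — strong LD within blocks, none between — is what the clumping and
scoring logic needs, and tests assert that contrast rather than an exact
level. Simulated panels contain no palindromic (A/T, C/G) SNPs, so
harmonisation drops none of them silently.

Two phenotypes are built from partially shared causal SNPs: a
`prop_shared` fraction of the smaller causal set affects both traits with
effect sizes correlated at `shared_effect_corr` (default 0.9); each genetic
value is rescaled to its target SNP heritability and completed with
Gaussian noise. Trait-exclusive causal SNPs are placed in disjoint loci
(runs separated by ≥500 kb), so `prop_shared = 0` yields genuinely
independent genetic values — without this, cross-trait signal leaks through
linkage between the two traits' causal SNPs and the null is miscalibrated.
Marginal GWAS summary statistics are per-SNP simple regressions (exact
t-test p-values); monomorphic SNPs are flagged and excluded downstream.

## Polygenic scores

Clumping follows standard practice: SNPs with MAF ≤ 0.03 are removed,
the rest visited in ascending p-value order (ties by position then id), and
a SNP is kept unless an already-kept SNP on the same chromosome within
±200 kb has squared Pearson dosage correlation > 0.25. r² is computed on
dosages, not haplotype D′, since that is what genotype-panel clumping tools
use. Scores at threshold t sum beta × effect-allele dosage over retained
SNPs with p < t over the eight standard thresholds (0.001–0.5). Ancestry
PCs come from the SVD of the standardised dosage matrix with
deterministic sign (largest-magnitude loading positive). "Variance
explained" is incremental r² — full model minus covariate-only model — the
conservative reading; the per-threshold p-values are deliberately left
uncorrected across the eight thresholds, and the result table says so in
its metadata.

## Phenotype preparation

Spherical equivalent is sphere + cylinder/2 per eye, averaged over eyes;
myopia is mean SE ≤ −0.75 D (boundary inclusive). Cylinder is validated as
minus-convention; plus-cylinder rows are transposed (s+c, −c) with a logged
warning (SE is invariant under the transposition). Standardised residuals
are OLS residuals on age and a sex indicator scaled to unit population SD,
so the output has mean 0 and SD 1 exactly and is exactly orthogonal to the
covariates. Association models adjust for twin relatedness with
cluster-robust (sandwich) standard errors over pair ids — this keeps all
individuals and corrects inference only; a seeded one-twin-per-pair
subsample is available as a sensitivity variant. IQ quartiles are cut on
the standardised distribution with boundary ties assigned to the lower
quartile; the top-vs-bottom quartile odds ratio is a logistic fit whose
unadjusted form equals the 2×2 cross-product ratio exactly, and complete
or quasi-complete separation raises an error instead of returning an
unbounded estimate.

## Problem sizes and numerical choices

The parameter-recovery experiment uses 5000 MZ + 5000 DZ pairs. At that
size the Fisher information puts the sampling SD of the standardised
components at ~2.2–2.8 percentage points, so single-experiment recovery is
dominated by Monte-Carlo noise; the acceptance script therefore averages 20
independent replicate experiments (per-experiment design unchanged) and
reports the total n. Constrained ML has a known downward boundary bias of
~1–1.5 points in trait-1 heritability here because the true C₁ (0.5%) sits
essentially at the zero boundary. The phenotypic-correlation check pools
both twins of 10,000 pairs, averaged over 4 replicates. PRS experiments use
hundreds of individuals and ~100–800 SNPs — large enough for the r² and
calibration properties under test, far below GWAS scale.

Degenerate inputs fail loudly: single-zygosity twin data (A and C not
separable), zero-variance traits, rank-deficient designs, k ≥ rank in the
PCA, infeasible calibrations and non-integer dosages in VCF output all
raise with diagnostics. Every stochastic routine takes an explicit integer
seed and is bit-reproducible; the pipeline writes byte-identical
`results.json` for identical configurations.

## What the synthetic data does and does not show

The generators emulate the *statistical structure* the methods consume:
ACE covariance algebra with exact moments, LD-block dosage panels,
marginal GWAS summaries with correct null behaviour, and pleiotropic
architectures with a controllable shared fraction. They do not emulate
cohort ascertainment, genotyping error, imputation, real LD patterns,
assortative mating, or gene–environment interplay. Passing tests therefore
demonstrate that the estimators recover known truths under the model's own
assumptions and that the pipeline's logic (clumping, harmonisation,
thresholding, covariate adjustment) is correct — not that the biological
point estimates would replicate in a real cohort. Real-cohort quantities
that depend on proprietary genotypes (e.g. specific PRS SNP counts and
variance fractions) are out of reach by design and covered instead by the
property-based checks above.
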