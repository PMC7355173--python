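# Methods

## The statistical model

The unit of inference is the gene.  For every SNP *j* (additive
minor-allele dosage g ∈ {0,1,2}) and a chosen exposure E, the package
fits, on complete cases per SNP,

y = β₀ + β_g g + β_e E + β_gxe (g·E) + Σ_c β_c c + [Σ_c β_cg (c·g) + β_ce (c·E)] + ε

by ordinary least squares, where c ranges over the covariates (age and
sex by default) and ε is homoscedastic Gaussian noise.  The two-sided
p-value of β_gxe comes from a Student-t with n_used − n_columns
degrees of freedom.  The bracketed covariate-by-G and covariate-by-E
product terms are included by default (`keller_terms=True`): omitting
them can leak confounder-interaction signal into β_gxe.  Since the
original analytic choice is ambiguous on this point, the flag can be
turned off; interaction p-values are invariant to affine rescaling of
the exposure either way.

Within a gene with k usable SNPs, Fisher's statistic T = −2 Σ ln pᵢ is
referred to a scaled chi-square c·χ²_f with

Var[T] = 4k + 2 Σ_{i<j} cov_ij,  c = Var/(2·2k),  f = 2(2k)²/Var,

cov_ij approximated by the Kost–McDermott cubic
3.263ρ* + 0.710ρ*² + 0.027ρ*³ clamped to [0, 4], the admissible
covariance range for χ²₂ margins.  ρ* is |r| of the dosage LD by
default: the dependence of two-sided p-values is symmetric in the sign
of the underlying statistic correlation, and dosage r is the available
proxy for it.  A signed-ρ variant (negative correlations contribute
zero after clamping) is exposed for comparison with implementations
that use signed r.  The survival probability is evaluated as
Gamma(shape f/2, scale 2c) at T, which handles non-integer f exactly.
Two limits are exact and continuously tested: identity LD reproduces
Fisher's method to 1e−12, and k identical p-values under all-ones LD
return that p-value (c = k, f = 2).

Genes enter pooling only with ≥ 2 usable SNPs (single-SNP "genes" add
nothing over the SNP test); degenerate SNPs (monomorphic, constant
exposure, rank-deficient designs at a relative singular-value
tolerance of 1e−10) are dropped from their gene with the LD matrix
subset accordingly.  Family-wise control is Bonferroni over tested
genes.  With 274 genes at α = 0.05 the threshold is 1.8 × 10⁻⁴ at two
significant digits.

## Validation layers

**Permutation.**  The gene-level null is rebuilt by permuting the
outcome vector (default) or the exposure, re-running scan → pool, and
counting permuted pooled p-values ≤ the observed one; the empirical
p-value is (1 + b)/(1 + B), which is never zero.  Outcome permutation
is the default because it is valid under the complete null and lets
the per-SNP design factorizations be reused — the engine factorizes
each design once (SVD) and scores each permutation with two matrix
products per SNP, so 1,000 permutations of an 80-gene cohort run in
seconds.  Exposure permutation rebuilds designs each round and is
correspondingly slower.  Which vector the original analysis permuted
is not documented; both are provided and neither is labelled
canonical.  Desk-scale default is 1,000 permutations; the published
protocol's 100,000 is reachable through configuration.

**Genomic control.**  λ = median(Q_{χ²₁}(1 − pᵢ)) / 0.4549364 over the
gene p-values.  λ is reported diagnostically only; no rescaling is
applied.  Two properties matter for interpretation and are measured by
the calibration studies rather than assumed: (i) the median-based
estimator is noisy — over m = 200 independent null p-values its
sampling sd is ≈ 0.165, so single-cohort λ routinely leaves
[0.9, 1.1] even for a perfectly calibrated statistic; (ii) interaction
tests within one cohort share the outcome and exposure vectors, which
correlates p-values across genes and roughly doubles that spread when
the exposure is strongly skewed.  Large single-cohort λ values in
interaction scans of rare exposures are therefore expected behaviour,
not necessarily evidence of confounding.

**Sensitivity to exposure skew.**  A rare harsh exposure concentrates
at the scale floor; `dichotomize_exposure` maps it to presence/absence
either by median split (ties at the median → 0, so a floor-massed
variable splits exactly at "no presence" vs "any presence") or by an
explicit scale-floor threshold, and the whole scan → pool → λ chain is
re-run unchanged.

## The synthetic cohort generator

The generator emulates the cohort structure this analysis assumes:
n = 948 individuals by default; genes of ≥ 2 SNPs; age ~ N(13.78,
0.92²); sex ~ Bernoulli(0.505); five exposures on a 1–5 questionnaire
scale.  Genotypes are built from two independent haplotypes per
individual; each haplotype thresholds a latent Gaussian with AR(1)
correlation ld_rho along the gene's SNPs at the normal quantile of the
SNP's MAF (drawn uniformly from the gene's MAF range, 0.05–0.5 by
default).  This construction was chosen over a genotype-level Gaussian
copula because summing two independent haplotypes guarantees
Hardy–Weinberg equilibrium exactly, and the single AR(1) parameter per
gene yields realistic decaying LD blocks.  Bounded-normal exposures
are Gaussian clipped to [1, 5]; the right-skewed exposure places a
point mass (default 55%) exactly at the floor plus a clipped
1 + Gamma(1.2, 0.9) tail, so its median equals the scale minimum and a
median split coincides with presence/absence.  The published source
does not print the questionnaire-scale means/SDs, so the exposure
location/scale defaults (e.g., bounded-normal mean 3.0, sd 0.8) are
placeholders chosen to be plausible for 1–5 scales, not estimates.  An
optional missingness injector (default 0) exercises the call-rate
filter.  The phenotype is the linear model above with configurable
coefficients; when a target gene is set, β_g and β_gxe apply summed
over all its SNPs.

What the generator does **not** emulate: family/sibling structure,
population stratification, genotyping batch effects, item-level
questionnaire scoring, and LD between genes.  Passing calibration on
these cohorts therefore shows the statistical machinery is correct
under its own assumptions, not that real cohorts are free of the
confounding those features can cause.

`gxe_beta_for_power` sizes an interaction coefficient for a requested
single-SNP power by estimating the residual variance of the g·E
regressor on a seeded 20,000-sample Monte-Carlo probe and inverting
the two-sided t-test power relation — used by the signal-recovery
study so "power ≈ 0.8 at n = 948" is a property, not a hand-picked β.

## Quality control

SNPs are filtered in the order call rate → MAF → HWE with strict
inequalities: call rate < 0.98 and MAF < 0.01 are excluded (call rate
counts individuals; MAF counts alleles among non-missing genotypes,
folded to ≤ 0.5).  The HWE filter defaults to α = 1e−6 — the
conventional GWAS choice; the source protocol states only that all
SNPs passed HWE, so the filter is optional (α = 0 disables it) — with
a 1-df chi-square test by default and an exact conditional test
(enumeration over heterozygote counts, no mid-p) available.  Reports
list every SNP with its metrics and first failing filter; the filters
are idempotent and the gene map is pruned with the genotypes.

## Numerical choices

- OLS via SVD; rank deficiency declared at s_min/s_max ≤ 1e−10;
  degenerate SNPs are skipped, never errors.
- p-values floored at 5e−324 (smallest subnormal) so logs stay finite;
  −log₁₀ p in Manhattan tables floored at 1e−300.
- LD matrices: pairwise-complete Pearson r of dosages, diagonal forced
  to exactly 1, clipped to [−1, 1]; near-PSD is accepted (the pooling
  formula needs only pairwise correlations).  `.ld` files asymmetric
  beyond 1e−6 are rejected; smaller asymmetry is averaged away.
- Kost–McDermott covariance clamped to [0, 4] to prevent negative
  pooled variances from sampling noise in r.
- Seeds: every stochastic stage takes an explicit seed; replicate
  studies derive 31-bit child seeds from a base seed via a fixed
  affine map, so any run is replayable and independent of scheduling.

## Study sizes and measured characteristics

The calibration studies (also run by `scripts/acceptance.py`) use
desk-scale problem sizes chosen to keep a full run in minutes on one
CPU while retaining the cohort dimensions the generator targets:
100 replicate null cohorts of 948 samples × 200 genes for type-I error
and λ; one 80-gene independent-SNP cohort with 1,000 permutations for
permutation consistency; 50 replicate 50-gene cohorts for signal
recovery.  Measured on these conditions: gene-level type-I error at
α = 0.05 ≈ 0.04–0.05 (the pooled estimate over 20,000 gene tests);
Spearman(analytic, permutation p) > 0.99; an injected 4-SNP gene sized
for 0.8 single-SNP power ranks first and clears Bonferroni in ≈ 95% of
replicates.  Single-cohort λ lands in [0.9, 1.1] in well under half of
null replicates, for the estimator-noise and shared-vector reasons
above — the package reports the λ distribution rather than asserting a
tight band per cohort.

## Known limitations

- The Kost–McDermott cubic is an approximation; at strong LD the
  pooled test is mildly conservative (measured rejection ≈ 0.03–0.04
  at nominal 0.05 for within-gene r ≈ 0.5–0.8).
- Dosage |r| proxies the interaction-statistic correlation; the exact
  correlation depends on the exposure distribution and covariates.
- Continuous outcomes and homoscedastic OLS only: no mixed models,
  robust errors, or binary outcomes.
- Exposure-permutation breaks exposure–covariate linkage; use
  outcome permutation when covariates matter under the null.
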