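# Methods

## Model

A bi-allelic SNP has reference allele A and coded allele B. Writing X_pat,
X_mat ∈ {0, 1} for the paternal and maternal B-allele counts, the phenotype
model is

    y = μ_AA + β_pat·X_pat + β_mat·X_mat + covariate terms + ε,
    ε ~ (0, σ²), σ² constant across genotype groups.

Homozygotes have means μ_AA and μ_AA + β_pat + β_mat and variance σ².
Heterozygotes are an even mixture of the A-pat/B-mat and B-pat/A-mat
subgroups, whose means differ by δ = β_pat − β_mat; with W ~ Bernoulli(½)
indicating maternal origin of B, the mixture mean is μ_AA + μ (where
μ = (β_pat + β_mat)/2 is the ordinary additive effect) and its variance is

    σ²_AB = σ² + δ²/4.

Parent-of-origin effects are therefore detectable in unrelated samples as
heterozygote variance excess, even under polar overdominance
(β_pat = −β_mat), where every genotype group has the same mean.

## The variance test

Per SNP, within each analysis stratum:

1. Centre the phenotype at its genotype-group median m_g (hard groups by
   max-probability call; under imputation, weighted medians with weights
   p_ig). Median-centering removes marginal mean effects so they cannot
   masquerade as variance differences in the pooled homozygote group.
2. Form expected absolute deviations z_i = Σ_g p_ig·|y_i − m_g|.
3. Regress z on the heterozygosity covariate x_i = p_i(AB) by OLS. The
   slope b is the het-minus-hom difference in mean absolute deviation
   (exactly, for hard calls); b/SE(b) is referred to Student t with n−2
   degrees of freedom, two-sided.

Absolute deviations from medians (rather than squared deviations from
means) make the test robust to non-Gaussian tails; a t(5) null keeps the
empirical size below 0.08 at α = 0.05 in the test suite. The t reference
(not the normal) matters only at small n but lets small fixtures behave
exactly. Degenerate probability triples reproduce the hard-call statistic
to machine precision, so GT, GP and integer-DS encodings of the same calls
are interchangeable.

QC defaults: a SNP is skipped when n < 30 or the effective heterozygote
count Σ p_i(AB) is below 50 (reason codes `n_too_small`, `n_het_eff`,
`monomorphic`). The het-count floor guards the group-variance estimates;
there is no information-score or MAF filter.

Weighted medians use cumulative-weight interpolation: with equal weights
and an even group the result is the mean of the two central order
statistics. A genotype group carrying zero probability mass (e.g. no B/B
individuals at a rare allele, or a recessive coding with no homozygotes)
gets a placeholder median, which is harmless because the group contributes
zero weight to every deviation.

## Phenotype preparation

Within each sex stratum the raw trait is residualised by OLS on intercept,
age and age², then standardised to zero mean and unit sample variance, so
all effect sizes are in phenotype-SD units. Strata below 10 individuals are
dropped. Sex-combined results are the fixed-effect meta-analysis of the
per-sex strata treated as independent studies.

## Meta-analysis, selection, pruning

Fixed-effect inverse-variance weighting: β = Σ(b_k/se_k²)/Σ(1/se_k²),
se = (Σ 1/se_k²)^(−1/2), two-sided normal P. A utility back-derives a
standard error from a published (β, P) pair via se = |β|/Φ⁻¹(1 − P/2),
used when combining printed per-study results.

Candidates satisfy (strictly) P < 5×10⁻⁶ genome-wide, or P < 5×10⁻⁴ within
500 kb of a known imprinted region (BED intervals, 0-based half-open; SNP
positions 1-based). Lead pruning is greedy in ascending P (snp_id
tie-break): a candidate survives only if it is > 1 Mb from, and has
r² ≤ 0.1 with, every already-kept lead, r² being the squared Pearson
correlation of expected coded-allele dosages p(AB) + 2·p(BB). The
effective number of independent tests is the smallest k whose top-k
correlation-matrix eigenvalues reach 99.5% of the trace; a 1e-9·trace
tolerance keeps exact-boundary cases at their exact-arithmetic answer.

## Family replication (PAT)

In trios or parent-offspring pairs, the origin of a heterozygous
offspring's B allele is forced whenever the observed parents cannot both
have supplied the same allele (at least one homozygous parent, or a
homozygous single parent). The assignment enumerates transmission
compatibility and returns one of PATERNAL_B / MATERNAL_B / AMBIGUOUS /
NOT_HET / MENDEL_ERROR / MISSING; probabilistic genotypes are hard-called
at 0.9 max-probability, below which they count as missing. Mendelian-error
families are excluded per SNP and counted.

At most one informative offspring per family contributes (smallest iid
among the eligible — an arbitrary but deterministic rule), with phenotypes
prepared study-wide exactly as in the discovery stage. The PAT compares
the two origin groups with a pooled-variance Student t-test (Welch by
flag); the group-mean difference estimates δ and feeds the same
inverse-variance meta-analysis for multi-study replication, with a strict
Bonferroni pass rule p < FWE/m.

## Effect sizes

Given the family-based δ and an external marginal effect μ (the package
never fetches it): β_pat = μ + δ/2, β_mat = μ − δ/2. With allele frequency
p on a unit-variance trait, knowing parental origin the SNP explains
2p(1−p)(β_pat² + β_mat²) of the variance — symmetric in p ↔ 1−p and in the
two parental effects.

From unrelated samples alone, T = s²_AB − (s²_AA + s²_BB)/2 estimates δ²/4
without bias, with Var(T) ≈ 2s⁴_AB/(n_AB−1) + ½[s⁴_AA/(n_AA−1) +
s⁴_BB/(n_BB−1)] under approximate Gaussianity. |δ̂| = 2√max(T, 0) is
strongly winner's-curse inflated when computed on the data that selected
the SNP (the test suite demonstrates the conditional bias), which is why
family-based δ estimates are preferred for reporting.

## Artefact diagnostics

Heterozygote variance excess has non-POE explanations; three checks guard
against them. (a) Overdominance: regression of the phenotype on p(AB)
(equivalent to the pooled het-vs-hom t-test for hard calls); flag at
α = 0.05. (b) Variance-vs-dosage: the absolute deviations regressed on
additively / dominantly / recessively coded dosage instead of the het
indicator; if any coding beats the POE test's P, the signal likely tracks
dosage (GxE-type variance), flag GXE_DRIVEN. (c) Transform robustness: the
POE test rerun after log and rank-based inverse-normal (Blom offsets,
average ranks for ties) re-expression, each re-residualised and
re-standardised; if −log10 P varies by more than a factor 10 (configurable)
across transforms, flag TRANSFORM_FRAGILE.

The Taylor tool quantifies check (c): for Gaussian Y and a twice-
differentiable transform f, Var f(Y) ≈ f′(m)²σ² + ½f″(m)²σ⁴ at group mean
m, and the het-minus-hom difference of these predictions shows how a
marginal effect a on a curved scale mimics a POE. For the logistic sigmoid
scale·(1+e^(−λ(y−c)))⁻¹ the predicted inflation grows without bound in the
steepness λ, so *any* marginal effect can be made to look like an
arbitrarily strong POE by an unfortunate trait scale. The second-order
prediction of the *difference* is accurate to ~5% for σλ ≲ 0.25 and
degrades quickly beyond σλ ≈ 0.4; the sweep demonstrating unboundedness
uses λ large enough (λa ≫ ln λ) that the homozygote curvature term has
decayed.

Because OVERDOMINANT fires at its nominal 5% rate even on a clean
polar-overdominant hit, a flag is a prioritisation signal, not a veto.

## Simulator

`simulate_cohort` draws paternal and maternal alleles independently
Bernoulli(p) (HWE), ages uniform on 30–70 y, sex Bernoulli(½), and applies
the model above. Defaults: n = 20,000; MAF 0.3; β_pat = +0.31,
β_mat = −0.31 (δ = 0.62, matching a het-hom variance excess of ≈0.095 on a
unit-variance trait — the magnitude of the discovery-stage signal at the
replicated loci); σ = 1; mild covariate structure (0.02/yr age, −0.0002/yr²,
+0.1 SD male) that the preparation step must remove. Imputation
uncertainty blends the true genotype's degenerate triple with the HWE
prior at weight 1 − info, which keeps E[p(AB)] calibrated; real imputation
error is genotype-correlated and LD-driven, so tests passing under this
model say nothing about info-score-dependent biases. SNPs are independent
(no LD) except the explicitly constructed correlated pairs used in pruning
tests — another idealisation relative to real data.

`simulate_trios` draws HWE parents and uniform transmissions; all
randomness sits in one fixed-layout uniform block per family so growing the
family count never reshuffles earlier families. Trio defaults plant
δ = 0.11 (the replicated family-study effect size).

Named scenario suites (`build_suite` / `make_fixtures`): `tiny` (50
individuals, parser exercises), `null`, `poe` (planted δ = 0.62 SNP among
50 nulls, n = 20,000 — at this size the planted SNP tops the sex-combined
meta-analysis in ≈96% of replicates), `gxe` (residual SD √(1 + 0.3·dose)),
and `transform` (additive SNP observed through exp). Problem sizes in the
test suite (e.g. 2,000 null replicates at n = 5,000 for size calibration;
200 replicates at n = 50,000 for the δ²/4 identity; 500 trio studies of
800 families for PAT unbiasedness) were chosen so Monte-Carlo error is well
below each assertion's tolerance.

## Known limitations

* Quantitative traits only; the variance footprint has no binary-outcome
  analogue.
* No relatedness or population-structure correction; strata are assumed
  independent in the meta-analysis.
* Variance-based δ estimates from discovery data are winner's-curse
  inflated; report family-based estimates.
* The genome-wide effective-test count of real LD panels is not
  reproducible from synthetic correlation matrices; the estimator is
  validated structurally only.
* DS-only genotype input is usable only for integer dosages: p(AB) is not
  recoverable from a fractional dosage without GP.
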