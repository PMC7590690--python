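# Methods

## Phenotype scoring

The signature score discretizes each gene against its cross-sample mean
(+1/−1/0) and sums over the signature.  "Unchanged (0)" is exact equality
with the mean — a measure-zero event for continuous data — because any
tolerance band would need an arbitrary width.  Classification thresholds
are strict inequalities at ±G/2 for a G-gene signature (±80 at G = 160);
when signature genes are missing from a matrix they are dropped with a
warning and G shrinks, so the thresholds track the effective signature.
The continuous *signature expression* used in every correlation analysis
is the per-sample **median** of signature-gene log2 values (configurable
to mean); the score itself is too coarse for correlation work and the
mean is sensitive to single outlying genes.

## Normalization

`upper_quartile_normalize` scales each sample by (mean of per-sample 75th
percentiles of **nonzero** counts)/(own 75th percentile) — the upper
quartile is computed over nonzero counts, the standard convention for
sparse count data.  `tmm_cpm` implements the trimmed-mean-of-M-values
estimator: reference = sample whose upper-quartile fraction is closest to
the cross-sample mean; per sample, M and A are computed over genes
nonzero in both sample and reference; genes outside the central 40 % of M
(trim 0.30) or central 90 % of A (trim 0.05) are excluded; the factor is
2^(precision-weighted mean of retained M) with inverse asymptotic
binomial variance weights, and factors are centered to geometric mean 1.
These trims and weights are the method's canonical defaults, and the
implementation agrees with edgeR 4.0.16 `calcNormFactors` to 1e-9 on a
shared fixture (frozen in the test suite).  CPM = counts/(library size ×
factor) × 1e6.  The low-expression filter removes genes whose **median**
CPM across samples is ≤ the threshold (inclusive, default 3); the
per-gene aggregator is configurable since different pipelines summarize
differently.  log2 uses pseudocount 1.

## Mutation enrichment

NSSM status is decided by a classification vocabulary shipped as a YAML
config (MAF dialect: missense/nonsense/nonstop SNVs, frameshift and
in-frame indels, splice site → true; silent/UTR/intron/IGR/RNA → false);
unknown tokens count as non-NSSM with a one-time warning.  TMB counts
NSSM **variants**, the binary matrix counts **genes**, so TMB ≥ mutated
genes always.

The per-gene model is logit P(non-inflamed) = β₀ + β₁·mutated +
β₂·log₁₀(TMB+1), maximum likelihood, Wald two-sided p on β₁.  Response
coding non_inflamed = 1 means positive β₁ = enrichment in non-inflamed
tumors; this is stated in every output header.  The +1 offset in the TMB
transform admits TMB = 0.  Non-convergent or separated fits are reported
with p = NA and excluded from the FDR family rather than penalized — the
estimator stays the plain model.  Frequency filters use strict "<"
exclusion (a gene at exactly 5 % / 0.5 % is tested).  FDR families: within
each tumor type for per-type runs, across all tested genes for
pan-cancer runs.

## Differential expression and activation

Per-gene two-group linear model on log2 expression.  Precision weights:
an unweighted first pass gives residual SDs; lowess (span 0.5) of
√SD against mean abundance yields a mean–variance trend, evaluated at
each observation's fitted value; weights = trend⁻⁴.  Gene variances are
then moderated by empirical-Bayes shrinkage toward a scaled-F prior
(moment matching on log variances; the prior df solves a trigamma
equation by Newton iteration), and the moderated t uses df residual +
prior.  With weights and moderation off the statistic reduces exactly to
the pooled two-sample t (asserted to 1e-10).  Per-sample "quality
weights" are not estimated — a deliberate simplification; with them DEG
lists on heterogeneous cohorts would be somewhat more sensitive.  Fold
change is reported on the linear scale with the signed convention
(down = −2^|Δ|) and significance is FDR < 0.05 **and** |FC| ≥ 1.5
(inclusive).

The hypergeometric overlap universe is the set of genes actually tested
for DE after filtering, not the genome: commercial curated knowledge
bases each define their own (non-reproducible) universe, whereas the
tested gene set is a declared, reproducible choice.  The activation z
uses unit weights over targets that are significant DEGs, so
|z| ≤ √n_overlap; selection thresholds are strict (p < 0.05, z > 1.95).
Pathway-to-pathway edges count shared **activated** regulators.

## Burden, heterogeneity, regression

The per-sample pathway activation call — needed to count "pathways active
in this sample", which group-level activation does not define — is: a
pathway from the stratum's activated list is active in a sample when the
sample's pathway expression (median over the regulator's targets) exceeds
the within-stratum median.  This is a declared substitute rule, not a
reconstruction; a z-threshold variant is configurable.  Category
distributions use cap 10 (min(score, 10)); the burden–expression
regression uses **uncollapsed** scores, keeps categories with ≥ 10
samples, takes the per-category median expression, and screens degree-2/3
polynomials against the linear fit with a Gaussian likelihood-ratio
chi-square (df = degree difference).  The chosen model is the lowest
degree not beaten at p < 0.05.

Heterogeneity: per-type category-percentage vectors, Euclidean distance
from the arithmetic-mean distribution, and a two-sided two-sample KS test
between the NSSM-distance and pathway-distance samples (exact p for
small samples).  Note the KS has one observation per tumor type, so its
resolution is set by the number of types, not the number of samples.

## Synthetic cohorts

The generator draws a latent inflammation axis λ ~ N(0,1) per sample and
builds every data type from it.  Defaults (the package's study
conditions, chosen once):

| parameter | default | why |
|---|---|---|
| types × samples | 10 × 60 (n = 600) | many-type structure at desk scale; the heterogeneity KS needs ≥ ~10 types for resolution |
| signature genes / effect | 160 / 1.0 log2 per SD λ | canonical signature size; effect makes score–λ Spearman ≈ 0.99 while groups stay ~25/50/25 % |
| pathways × targets / effect | 5 × 20 / −1.0 log2 per SD λ | programs anti-correlated with inflammation, detectable per stratum |
| pathway pattern | heterogeneous (type *t* gets an increasing prefix of live programs) | plants between-type heterogeneity deterministically |
| mutation panel | 60 recurrent genes, prevalence U(0.05, 0.25) | realizes TMB as a sum of Bernoullis; panel size set by power analysis so BH at FDR 0.10 retains ≥ 0.8 sensitivity for the planted OR |
| flagged genes | 3, OR 4, prevalence 0.10, TMB coupling 0.5 | genuinely phenotype-linked on top of burden |
| confounder genes | 3, prevalence 0.15, coupling 3.0 logits per log10(TMB+1) | exactly null given TMB; coupling sized so the unadjusted association is reliably detectable at n = 600 |
| TMB propensity | log10 base 1.2, type spread ±0.2, SD 0.25, λ-coupling 0.25 | inflamed tumors modestly higher burden — the confounding channel |
| noise SD / baseline | 1.0 / N(7, 1) log2 | bulk-RNA-like dispersion |
| response model | logit P(R) = 0 + 1.5·λ | responders enriched among inflamed samples |

Mutation probabilities are **logit-linear in log10(realized TMB + 1)** —
the exact covariate the enrichment model adjusts for — so confounder
genes are null by construction under adjustment.  Decoy regulators
(genuinely DE targets, random edge signs) give the activation z a
non-trivial null operating point.  The "true" phenotype for planting
mutation effects thresholds λ at ±0.67 SD (matching where the score
thresholds land); the observed phenotype always comes from scoring.  RNG
is counter-based (Philox), so a seed reproduces a cohort bit-for-bit.

**What the generator does not emulate:** gene–gene correlation beyond the
planted programs, mutational signatures and hotspots, copy number,
count-level noise (expression is generated on the log2 scale directly, so
normalization is exercised on separate count fixtures), batch effects,
and realistic per-type sample imbalance.  Passing recovery tests
therefore demonstrates the estimators do the right thing under the
assumed mechanisms — not that real cohorts satisfy those mechanisms.

## Numerical notes and limitations

* Exact two-sample KS p-values are discrete; at 30-vs-30 the null
  rejection rate at α = 0.05 is ~0.04 (valid, mildly conservative).
  Calibration tests assert tail validity rather than literal uniformity.
* Logistic separation is detected by non-convergence or |β| > 15 /
  SE > 50 and reported as NA rather than estimated.
* With ~3 planted genes at OR 4 and prevalence 10 % in n = 600, per-gene
  recovery power at FDR < 0.10 is ~0.85, so pooled sensitivity clears
  0.8 but "all three in one run" happens only ~70 % of the time — a
  property of the effect size, not of the estimator.
* The per-sample pathway call forces ~50 % activity per live pathway
  within a stratum; pathway scores therefore measure *how many* programs
  a stratum has live much more than within-stratum grading.
* Welch's test, Pearson/Spearman correlation, Fisher's exact test, BH
  adjustment, logistic/OLS fits, and lowess come from scipy/statsmodels;
  the scoring, TMM, activation z, moderated DE, and heterogeneity
  statistics are implemented here and each is tested against an
  independently coded oracle (brute force, enumeration, closed form, or
  an external reference implementation).
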