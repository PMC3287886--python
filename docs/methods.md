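# Methods

## Scope and model

`generank` scores genes, not markers. Every endpoint is analysed under an
additive genetic model with a fixed covariate adjustment: Q1 (linear,
adjusted for Q2, age, sex, smoking), Q2 (linear, adjusted for Q1, age,
sex, smoking) and AFF (logistic, adjusted for Q1, Q2, Q4, age, sex,
smoking). Adjusting each quantitative trait for the other removes shared
covariate-driven variance and sharpens the genetic signal; the binary
endpoint is additionally adjusted for the quantitative traits because they
act as intermediate phenotypes on its liability.

Marginal fits produce Wald statistics `t = beta/se` per marker. The gene
scores are:

* **MS** — `max_j |t_j|`. Two-sided by default because effects may have
  either sign in general data; no adjustment for the number of markers, so
  MS behaves like single-marker screening. Its null distribution is an
  order statistic of correlated variables, so no analytic p-value is
  attached; permutation p-values are available instead.
* **HT** — `t' R^- t` with `R` the Pearson correlation matrix of the
  gene's genotype columns and `R^-` its pseudo-inverse (rcond 1e-10).
  Genotype correlation (not statistic correlation) is used: the marginal
  statistics share one phenotype vector, and under the null their
  correlation equals the genotype correlation. df = rank(R); a chi-square
  reference p is stored but ranking uses the raw score.
* **MV** — likelihood-ratio statistic of the joint model with all gene
  markers against the covariates-only null; for linear models this is
  `n * log(RSS_null / RSS_full)`. Gene columns are pruned for collinearity
  greedily in marker order (a column is dropped when its residual variance
  after projection on the intercept, covariates and previously retained
  columns falls below 1e-10 of its own variance), which makes df and the
  fit deterministic.
* **LA** — deviance improvement of the L1-penalised joint genetic model
  over the null. Only genetic columns are penalised; the penalty is chosen
  by 10-fold cross-validated deviance (fold assignment seeded) at the
  minimum of a 100-point geometric lambda path down to `1e-4 * lambda_max`.
  The score uses the penalised fit's own deviance (no refit), so
  `LA <= MV` always, with equality at lambda -> 0.

Ties in ranking receive the average rank; missing scores rank last. The
power surrogate is the number of truly causal genes among the top N
(N = 10, 20, 50, 100, 200, 500 by default), averaged over phenotype
replicates.

## Dataset construction

In-sample MAF is `sum(g) / 2n`, flipped when above 0.5 (the minor allele
is then the reference allele). A variant is *common* when MAF > cutoff
(1% or 5%) and *rare* when 0 < MAF <= cutoff — a half-open split so no
variant is lost or double-counted at the boundary. CR datasets add one
supermarker per gene: the 0/1 indicator of carrying at least one minor
allele across the gene's rare **nonsynonymous** variants (indicator
collapsing; synonymous rare variants are discarded because collapsing aims
to enrich direct functional effects, while common variants of both classes
are kept for their linkage-disequilibrium information). The
fewer-than-five-minor-alleles filter is applied after collapsing and also
to supermarkers, because supermarkers are treated as markers everywhere
else; genes left without markers are dropped. Missing genotypes are not
imputed — VCF import fails fast on a missing GT.

## Synthetic data

The mini-exome generator emulates the structure of an exome-wide
association study of unrelated individuals, not any particular data set:
697 individuals by default; gene sizes categorical on 1–15 markers with
probability proportional to 1/size (most genes small, a tail of larger
ones); 75% of variants rare with MAF uniform on (0.0008, 0.01], the rest
uniform on (0.01, 0.5); 70% nonsynonymous; genotypes binomial(2, MAF)
under Hardy–Weinberg equilibrium. Causal genes (defaults 9/13/15 for
Q1/Q2/AFF, scaled to a few hundred genes) carry 1–4 causal nonsynonymous
markers with effects uniform on (0.2, 0.8) trait units per allele.
Q1 and Q2 are linear in their causal genotypes plus covariate effects
(age, sex, smoking, coefficient 0.25 on standardised/indicator scale) and
unit Gaussian noise; Q4 is covariates plus noise only (a nuisance trait
with no genetic component here); AFF thresholds a latent liability — its
own causal markers plus 0.5 times each standardised quantitative trait
plus noise — at the empirical quantile matching the configured prevalence
(0.3), so the realised prevalence is exact by construction. Genotypes are
simulated once and phenotype replicates re-drawn with fresh seeds, the
replicate design of mini-exome benchmark data.

What this generator does **not** emulate: linkage disequilibrium between
markers (columns are independent given their MAFs), population structure,
relatedness, genotyping error, and the long tail of very large genes.
Passing tests therefore demonstrate correctness of the statistical
machinery and the architecture-dependent method ordering, not performance
on real LD-structured data.

The case-control generator draws, per cell of the scenario grid, a block
of null genes (2, 3, 5 or 7 markers each, allele frequencies uniform on
(0.05, 0.5) so every marker is a well-behaved "common or collapsed"
marker) whose genotypes are independent of status, plus one causal gene of
the same width whose first 1–3 markers act through a logistic penetrance
with per-allele log odds ratio and baseline prevalence 0.01. Case and
control genotypes are sampled retrospectively from the exact
genotype-given-status distributions obtained by Bayes enumeration over
g in {0, 1, 2} (the penetrance intercept solved numerically so the
population prevalence is exact) — this matches the stated odds ratio
exactly, with no rejection sampling. The grid spans allele frequencies
{1, 5, 10, 20, 40}%, odds ratios {1.2, 1.3, 1.5, 1.7} and N = 300 or
1000 cases with equal controls; 2,000 null genes and 1,000 causal
replicates at full scale.

## Evaluation and characterisation

Scenario comparison fits, separately per endpoint and top-N cutoff, a
linear mixed model of the causal count on method (4 levels), cutoff
(1% vs 5%), rare-variant use, and the cutoff × use interaction as fixed
factors with a random intercept per simulation replicate (REML). Reported
contrasts: all six method pairs, cutoff (1% − 5%), use (common-only −
with-rare) with main effects evaluated at the average of the other factor,
and the interaction as the difference-in-differences. On a balanced design
these equal the mean paired differences exactly, which the tests assert to
1e-8. Constant factors are dropped from the design rather than producing a
singular fit.

Permutation p-values permute phenotype and covariate rows jointly —
preserving the phenotype–covariate association while severing all
genotype links, since covariates are confounder adjustments rather than
exposures — with one permutation stream shared by all genes, and use the
add-one convention `p = (1 + #{permuted >= observed}) / (B + 1)`.

Gene characterisation uses frequency-adjusted effect sizes
`|beta| * sd(genotype)`, with `sd = sqrt(2 f (1-f))` for additive markers
under HWE and the empirical indicator SD for supermarkers (whose beta is
taken as the mean beta of the contributing causal variants — the indicator
approximates the average carrier effect). Method preference per gene
compares median ranks across replicates: ratio < 0.9 or > 1.1 declares a
clear winner; a gene is "undetectable" unless at least one method achieves
a median rank of 1,000 or better (smaller is better). Group
characteristics are compared with a two-sided Mann–Whitney test, exact
when there are no ties (the characteristics are skewed counts and ratios,
so a rank test is the safer default); for tied samples the asymptotic form
without continuity correction is used so identical groups give p = 1. The
mirror-consistency of the preference labels breaks down only inside the
ratio band [0.9, 1/0.9], an inherent asymmetry of a fixed multiplicative
band.

## Numerical choices

* Marginal linear fits use the Frisch–Waugh–Lovell projection (QR of the
  covariate block, then vectorised inner products) — exact OLS, validated
  against statsmodels to 1e-10 in the tests.
* Marginal logistic fits use Newton–Raphson with step-halving;
  coefficients beyond |25| are treated as separation and flagged, and the
  flagged marker is simply excluded from its gene's score. The
  intercept-plus-marker case is vectorised across markers.
* The lasso is a glmnet-style coordinate descent in Gram form (per-sweep
  cost independent of sample size, numba-accelerated when available) with
  per-column penalty factors, warm starts along the path, and IRLS with
  weights floored at 1e-5 for the logistic family. Convergence tolerance
  1e-9 on the standardised scale; coefficients below 1e-10 at the
  soft-threshold boundary are treated as zero.
* Hotelling uses `pinv(R, rcond=1e-10)`; for nonsingular R this equals the
  explicit inverse to 1e-8 (asserted over 1,000 random genes).
* Seeds: every stochastic component takes an integer seed; nested
  components derive child seeds as `SeedSequence([master, index...])`
  reduced below 2^31, so whole-pipeline runs are bit-reproducible.

## Problem sizes

Defaults are desk-scale: the replication study runs a few hundred genes
over a handful of phenotype replicates, and the crossover experiment uses
200 null genes with 100 causal replicates per cell; full-scale parameters
(2,000 null genes, 1,000 causal replicates, 200 phenotype replicates) are
plain configuration values. The acceptance script states the sizes it uses
alongside each quantity.

## Known limitations

* No LD in the exome generator (see above); LD enters only through the
  collapsing of rare variants into supermarkers.
* Logistic separation is handled by exclusion, not penalised refits, to
  keep the four methods comparable.
* MS carries no analytic p-value; use permutation p-values when calibrated
  significance (rather than ranking) is needed.
* The mixed model treats counts as Gaussian; for very small top-N counts a
  generalised model might be preferable, but the contrasts are used
  descriptively, mirroring the tabulated-comparison workflow.
* Only indicator collapsing is implemented; weighted or adaptive schemes
  are out of scope.
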