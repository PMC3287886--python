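# generank

Gene-wise scoring of common and collapsed rare variants for ranking
candidate causal genes in association studies.

## The problem

Genome-wide screens for complex traits must select a short list of genes
for replication from thousands of candidates, combining evidence from
common variants and from rare variants that are individually untestable.
`generank` implements and compares four gene-wise scores on additive
genotype data (0/1/2 dosage), with rare nonsynonymous variants optionally
collapsed into a per-gene carrier indicator ("supermarker"), and asks the
question a study designer cares about: *which score puts the most truly
causal genes near the top of the list?*

For a gene with markers $g_1, \dots, g_m$ (supermarker included), marginal
regression of the endpoint on each marker — linear for quantitative traits,
logistic for affection status, always with the covariate adjustment set —
yields Wald statistics $t_j = \hat\beta_j / \mathrm{se}(\hat\beta_j)$. The
four gene scores are

* **MS** (maximum statistic): $\max_j |t_j|$, unadjusted for the number of
  markers;
* **HT** (Hotelling's $T^2$): $t^\top R^- t$, where $R$ is the Pearson
  correlation matrix of the gene's genotype columns and $R^-$ its
  Moore–Penrose pseudo-inverse;
* **MV** (multivariate): the likelihood-ratio statistic
  $2(\ell_{\text{full}} - \ell_{\text{null}})$ of the joint model with all
  of the gene's markers against the covariates-only null;
* **LA** (LASSO): the deviance improvement of an L1-penalised joint
  genetic model over the null, with covariates unpenalised and the penalty
  chosen by K-fold cross-validation.

Genes are ranked by the raw score; the package evaluates rankings by the
number of truly causal genes among the top $N$, compares analysis
scenarios (method × rare-variant cutoff × rare-variant use) with a linear
mixed model, characterises which gene architectures favour which method,
and provides permutation p-values. A synthetic mini-exome generator and a
case-control scenario generator supply data with the statistical structure
the analysis assumes.

## Worked example

`examples/score_genes.py` simulates a 120-gene mini-exome (697
individuals), builds the CR1% dataset (common variants above 1% MAF plus
rare-variant supermarkers, markers with fewer than five minor alleles
removed) and scores every gene for endpoint Q1 with all four methods:

```
dataset CR1%: 100 genes, 9 truly causal for Q1
MS: 4 causal genes in the top 10 (best: GENE00107, GENE00036, GENE00022)
HT: 4 causal genes in the top 10 (best: GENE00107, GENE00036, GENE00022)
MV: 4 causal genes in the top 10 (best: GENE00107, GENE00036, GENE00022)
LA: 3 causal genes in the top 10 (best: GENE00107, GENE00036, GENE00022)
```

Four of the nine causal genes land in each method's top 10 — far more than
the 0.9 expected for random ranking — and the methods largely agree on the
leaders.

The characteristic divergence between MS and HT appears in the
case-control experiment (`examples/crossover_experiment.py`): one causal
gene of seven markers hidden among 300 null genes, 100 replicates:

```
1 causal marker(s): median rank MS = 55.5, HT = 78.0  ->  MS better
3 causal marker(s): median rank MS = 23.0, HT = 12.0  ->  HT better
```

With a single causal variant the maximum statistic concentrates on it
while $T^2$ dilutes the signal across the gene's null markers; with
several independent causal variants $T^2$ accumulates their joint evidence
and wins. The other examples cover simulation
(`simulate_mini_exome.py`), dataset construction (`build_datasets.py`) and
permutation p-values (`permutation_pvalues.py`).

A thin CLI wraps the same library calls:

```bash
generank simulate --seed 4 --out sim/
generank score --genotypes sim/genotypes.tsv --markers sim/markers.tsv \
    --phenotypes sim/phenotypes.tsv --method HT --endpoint Q1 --cutoff 0.01
generank crossover --null-genes 200 --replicates 100 --seed 1
```

## Layout

```
src/generank/     simulate, datasets, scoring, evaluation, characterize,
                  pipeline, io, cli (+ _glm / penalized numerical kernels)
examples/         one short narrative script per capability
tests/            pytest suite, including end-to-end acceptance checks
docs/methods.md   models, assumptions, parameter choices, limitations
```
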