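"""Simulate a mini-exome study: genotypes, truth table, one phenotype replicate.

The generator emulates an exome-wide association design of unrelated
individuals: genes of 1-15 markers, a MAF spectrum dominated by rare
variants, causal nonsynonymous markers for Q1/Q2/AFF, and covariates
age/sex/smoking.
"""

from generank import ExomeConfig, simulate_exome, simulate_phenotypes

cfg = ExomeConfig(n_genes=200, seed=7)
study, truth = simulate_exome(cfg)
phenotypes = simulate_phenotypes(study, truth, cfg, seed=1)

rare = (study.markers["maf"] <= 0.01).mean()
print(f"{study.n_individuals} individuals x {study.n_markers} markers "
      f"in {len(study.gene_ids)} genes")
print(f"fraction of rare (MAF <= 1%) variants: {rare:.2f}")
for endpoint in ("Q1", "Q2", "AFF"):
    genes = truth.causal_genes(endpoint)
    print(f"{endpoint}: {len(genes)} causal genes, "
          f"{len(truth.causal_markers(endpoint))} causal markers")
print(f"realised AFF prevalence: {phenotypes['AFF'].mean():.3f} "
      f"(configured {cfg.prevalence})")
# The truth table records which markers drive each endpoint and with what
# effect size; the analysis modules only ever see genotypes and phenotypes.
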