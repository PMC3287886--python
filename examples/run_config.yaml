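# Example configuration for `generank evaluate --config examples/run_config.yaml`
exome:
  n_individuals: 697
  n_genes: 150
  rare_fraction: 0.75
  nonsyn_fraction: 0.7
  prevalence: 0.3
  n_causal_genes:
    Q1: 9
    Q2: 13
    AFF: 15
run:
  replicates: 5
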