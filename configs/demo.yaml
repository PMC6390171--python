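# Demo run: synthetic two-cohort discovery (160 + 100 samples), two
# replication families, non-renal comparison tissues, and the full
# genotype/methylation/expression triangulation of the planted target.
seed: 1
simulate:
  scenario: promoter_methylation
  n_genes: 150
  discovery_sizes: [160, 100]
  replication_families:
    cortex: 150
    medulla: 150
  tissue_scenarios:
    primary: 2
    alternative: 3
  n_tissues: 2
  tissue_size: 120
  target_gene: gene_0000
  target_cpg: cpg_0000
  with_traits: true
preprocess:
  pseudo_count: 1.0
  blom_c: 0.375
  n_hidden_factors: 2
  n_genotype_pcs: 3
fdr:
  method: bh
  threshold: 0.05
replication:
  q_threshold: 0.05
qtl:
  eqtl_window: 1000000
  mqtl_window: 33172
  B: 1000
  maf_min: 0.05
  seed: 11
mediation:
  n_boot: 999
  seed: 12
mr:
  r2_max: 0.1
  p_max: null
  seed: 13
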