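# Demo pipeline configuration: a desk-scale emulation of the WT-vs-KO
# corpus-callosum study. Unknown keys are rejected; see docs/methods.md.
schema_version: 1
seed: 11
out_dir: results/demo
reference_label: WT
test_label: KO
q_threshold: 0.05
fc_threshold: 1.5
mds_k: 2
reference_gene: Rn18s
stages:
  simulate: true
  de: true
  enrich: true
  compare: true
  qpcr: true
study:
  n_genes: 2000
  n_samples_per_condition: 3
  noise_sd_log2: 0.25
  n_background_up: 150
  n_background_down: 40
signatures:
  n_genes: 500
  within_block_cosine: 0.9
  between_block_cosine: 0.2
  noise_sd: 0.1
qpcr:
  n_animals_per_group: 6
  n_technical_replicates: 3
  ct_noise_sd: 0.3
enrichment:
  n_permutations: 199
  weight_exponent: 1.0
  n_random_sets: 10
  random_set_size: 50
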