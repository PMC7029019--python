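# Example pipeline configuration for `ifomics run --config config.yaml`.
# Omit `synth` and set gene_tsv/metabolite_tsv/otu_tsv/metadata_tsv to run
# on your own matrices instead.
out_dir: ifomics_run
seed: 7
synth:
  n_per_group: [10, 11]
  seed: 7
rdcv:
  repetitions: 20        # protocol scale: 200
  outer_folds: 7
  inner_folds: 6
  max_components: 3
n_permutations: 50       # protocol scale: 1000
permanova_permutations: 199
rarefaction_depth: 28257
keepx: 10
n_components: 1
circos_threshold: 0.7
ancom_alpha: 0.05
coexpr_beta: 6.0
coexpr_min_module_size: 5
otu_integration: clr     # or css
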