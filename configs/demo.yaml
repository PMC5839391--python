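# Demo pipeline configuration: a fully synthetic study with a toy metabolic
# model, a planted -1.0 log2 effect on one functional module, and
# median-effect viability tables per cell-line stand-in.
seed: 1
simulate:
  toy_model:
    n_linear_reactions: 3
    n_parallel_branches: 2
    uptake_bound: 10.0
    genes_per_reaction: 1
  experiment:
    n_proteins: 120
    n_samples: 4
    n_conditions: 2
  annotation:
    module_00: 12
    module_01: 12
    module_02: 12
    module_03: 12
    module_04: 12
    module_05: 12
    module_06: 12
    module_07: 12
    module_08: 12
  effects:
    treated1:
      module_00: -1.0
  viability:
    m: 1.5
    Dm_base: 10.0
    doses: [0, 5, 10, 20, 40, 80, 160]
    noise_sd: 0.0
parameters:
  min_peptides: 2
  min_detect_frac: 0.75
  delta_threshold: 1.5
  n_branches: 10
  alpha: 0.05
  mc_samples: 20
  fva_fraction: 1.0
  change_frac: 0.95
  max_terms: 2
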