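inputs:
  simulate:
    seed: 7
grouping: soil_type
diversity:
  n_perm: 199
  seed: 11
network:
  seed: 12
robustness:
  n_iterations: 199
  seed: 13
stability:
  n_iterations: 49
  seed: 14
plspm:
  n_boot: 199
  seed: 15
output_dir: comstab_demo
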