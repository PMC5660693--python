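# Demonstration study: three preserved planted modules and one that
# decoheres in the NRM class (mirrors moanet.pipeline.demo_config).
out_dir: demo_out
seed: 3
cut_height_fraction: 0.98
n_permutations: 200
synthetic:
  n_genes: 2000
  noise_sd: 1.0
  moa_affected_fraction: 0.25
  moa_effect_sd: 0.8
  moa_factor_sd: 1.0
  chem_factor_sd: 1.0
  sample_factor_sd: 0.5
  modules:
    - {module_id: M1, size: 150, eigengene_loading_range: [0.75, 0.95]}
    - {module_id: M2, size: 120, eigengene_loading_range: [0.75, 0.95]}
    - {module_id: M3, size: 90, eigengene_loading_range: [0.75, 0.95]}
    - {module_id: M4, size: 60, eigengene_loading_range: [0.75, 0.95],
       preserved_in_test: false}
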