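# Synthetic multi-cell demo: 6 study cells, pooled segments, reduced
# bootstrap sizes so the whole run finishes in a couple of minutes.
output_dir: runs/demo
seed: 7
scenario:
  cell_side: 2400.0
  k_true: 3
  n_sites: 18
  individuals_per_site: 4
  theta_drift: 0.2
  effect_coefficients: {forest: 2.5, grassland: 8.5}
  noise_sd: 0.2
n_cells: 6
widths: [3.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 1000.0]
bootstrap_B: 100
retain_threshold: 90
validation_fraction: 0.2
validation_reps: 50
validation_widths: [100.0, 200.0, 400.0]
fst_permutations: 199
fis_permutations: 199
mantel_permutations: 199
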