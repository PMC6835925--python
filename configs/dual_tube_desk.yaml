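# Dual-tube selectivity/shadowing series at 10 mmol Fe/l, desk scale.
experiment: dual_tube
seed: 7
output_dir: runs/dual_tube_desk
scanner:
  scale: test
grid:
  shape: [13, 13, 13]
  voxel_size_mm: [1.5, 1.5, 0.75]
dual_pairs: [[3, 3], [2, 2], [3, 2], [3, 1], [2, 1]]
dual_concentration_mmol_l: 10.0
orientations: [x]
lambdas: [1.0e-1, 1.0e-2]
recon_iterations: 5
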