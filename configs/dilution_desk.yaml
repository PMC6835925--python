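# Desk-scale dilution series: single 3 mm tubes, two orientations,
# seven-decade regularization sweep on a 13^3 grid.
experiment: dilution_series
seed: 7
output_dir: runs/dilution_desk
tracer:
  beta: 0.73
  mu1_aAm2: 0.1852      # 10 nm equivalent-sphere moment at M_S below
  mu2_aAm2: 3.9
  sigma1: 0.30
  sigma2: 0.13
  ms_molar: 5.81        # Am^2/mol(Fe)
  temperature: 310.0
scanner:
  scale: test           # divisors (16, 15, 14) at 400 kHz sampling
  sf_snr_target: 100.0
  snr_threshold: 5.0
grid:
  shape: [13, 13, 13]
  voxel_size_mm: [1.5, 1.5, 0.75]
concentrations_mmol_l: [10, 5, 2, 1, 0.5, 0.2, 0.1]
orientations: [x]
lambdas: [1.0, 1.0e-1, 1.0e-2, 1.0e-3, 1.0e-4, 1.0e-5, 1.0e-6]
tube_inner_diameter_mm: 3.0
recon_iterations: 5
nonneg: true
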