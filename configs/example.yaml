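# Example run configuration for the petiq CLI.
# `seed` is mandatory; unknown keys are rejected.
seed: 1

# Numerical scale of the simulation (defaults shown; the scanner's axial
# layout is 47 slices/bed with an 11-slice overlap — the default 23/5 keeps
# the same 50% combined-overlap sensitivity at desk scale).
scale:
  n_pixels: 64
  in_plane_spacing: 5.0
  micro_spacing: 2.5
  angles: 96
  slices_per_bed: 23
  overlap_slices: 5
  subsets: 24
  osem_iterations: 2
  bpl_cap: 30
  bpl_tolerance: 1.0e-4
  calibration: 0.03

# Penalty-weight analogues (use petiq.experiments.calibrate_beta to anchor
# these against OSEM+PSF noise on your own simulations).
betas:
  low: 0.6
  mid: 0.73
  high: 0.93

contrast:
  ratio_cases: ["10:1", "4:1", "2:1"]

time_series:
  times_min: [1.0, 2.0, 3.0, 4.0, 5.0]

overlap:
  n_patients: 3

cohort:
  n: 8
  weight_range: [44.0, 75.0]
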