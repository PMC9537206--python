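# stenoflow configuration — all values shown are the defaults.
rheology:
  mu_zero: 0.056        # zero-shear viscosity, Pa.s
  mu_inf: 0.0035        # infinite-shear viscosity, Pa.s
  lambda_time: 3.313    # Carreau-Yasuda time constant, s
  n_index: 0.3568       # power-law index
  a_exponent: 2.0       # Yasuda transition exponent (2 = Carreau)
  density: 1060.0       # blood density, kg/m^3
  # newtonian: true     # use a constant-viscosity marker instead
  # mu: 0.0035          # constant viscosity when newtonian is true

waveforms:
  heart_rate: 70.0              # bpm -> period 60/70 s
  peak_velocity: 0.5            # peak cross-section-mean inlet velocity, m/s
  reverse_fraction: 0.15        # post-systolic backflow notch depth
  systolic_pressure: 120.0      # mmHg
  diastolic_pressure: 80.0      # mmHg
  systolic_time_fraction: 0.35  # fraction of the cycle in systole

geometry:
  radius_mm: 1.5
  length_mm: 30.0
  stenosis_center_mm: 15.0
  stenosis_length_mm: 4.0       # within the 2-6 mm focal-lesion range
  severity: 0.0                 # used by `stenoflow run` unless --severity given

grid:
  n_axial: 96
  n_radial: 24
  growth_rate: 1.2              # geometric near-wall clustering

solver:
  dt: 0.01                      # s (snapped to an integer step count per cycle)
  n_cycles: 3
  picard_tol: 1.0e-3
  picard_relax: 0.7
  div_tol: 1.0e-8
  max_inner_iterations: 30
  n_wss_samples: 100            # WSS export instants per cycle

pipeline:
  severities: [0.0, 0.25, 0.35, 0.50, 0.65]
  rrt_epsilon: 1.0e-3           # RRT singularity cap
  decay_fraction: 0.15          # diastole starts this far after the systolic peak
  write_vtk: false
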