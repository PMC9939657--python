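# Demo pipeline configuration: generate -> train -> benchmark.
# Every printed study constant appears here as a named default, so any
# deviation is a visible diff.  Run with:  hergfit run --config examples/demo_config.yaml
workdir: scratch/demo-run
seed: 1
n_train: 500
n_val: 50
n_cells: 10
protocol_csv: null          # null -> built-in staircase (15.4 s, 500 ms core steps)
sample_rate: 5000.0         # Hz
downsample_factor: 50       # 77,000 -> 1,540 samples
noise:
  sigma: 10.84              # pA, additive zero-mean Gaussian
prior:
  g_bounds: [100.0, 500000.0]        # pA/V
  prefactor_bounds: [1.0e-4, 1.0e+6] # 1/s
  sensitivity_bounds: [1.0e-4, 400.0] # 1/V
  rate_bounds: [0.0167, 1.0e+6]      # 1/s at the extreme voltages
  v_min: -0.12                       # V
  v_max: 0.06                        # V
regressor:
  backbone: small_mlp
  input_resolution: [129, 129]
  stage_schedule:
    - {resolution: [97, 97], n_examples: 300, epochs: 40}
    - {resolution: [129, 129], n_examples: null, epochs: 30}
  seed: 1
fit:
  sigma0: 0.03
  max_iter: 1000
  stagnation_tol: 0.01      # pA
  noise_sigma: 10.84        # pA, convergence classification floor
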