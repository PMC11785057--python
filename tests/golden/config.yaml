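mcmc:
  preheat_sweeps: 2000
  production_sweeps: 8000
synth:
  n_sequences: 50
run:
  seed: 2024
  mode: gcpbm
  out_dir: scratch/golden_run
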