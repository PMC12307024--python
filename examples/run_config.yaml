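# Example run configuration for the `rift` CLI.
# `rift run-all --config examples/run_config.yaml --seed 42 --out out/`
simulation:
  n_participants: 12
  n_trials_per_condition: 20
  seed: 42
  amp_audio: 1.0
  amp_visual: 1.0
  g_related: 0.3        # interaction gain, related condition
  g_unrelated: 0.6      # interaction gain, unrelated condition
  noise_sd: 1.0         # uV, 1/f background
  alpha_amp: 2.0        # uV, 10 Hz alpha
  participant_sigma: 0.4
  tag:
    f_audio: 54.0
    f_visual: 68.0
analysis:
  n_perm: 2000
  alpha: 0.05
  k: 6
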