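# Reduced-scale demo study: 8 subjects, three conditions, one
# hand-selective response plus one pattern shared by hands and tools.
# Runs end-to-end in about a minute on a laptop:
#   eegmvpa run --config examples/demo.yaml --out demo_run
seed: 20
simulation:
  n_subjects: 8
  n_trials_per_condition: 64
  conditions: [hands, tools, animals]
  n_scalp_channels: 16
  sfreq: 200
  epoch_window: [-500, 500]
  noise_sd: 1.0
  effects:
    - conditions: [hands]
      window: [100, 300]
      amplitude: 1.1
      topography: 3
    - conditions: [hands, tools]
      window: [250, 350]
      amplitude: 0.9
      topography: 7
  artifact_spec:
    trial_fraction: 0.05
    electrode_fraction: 0.06
    p2p_multiplier: 10
analysis_window: [-100, 500]
preprocessing:
  target_sfreq: 100
  band: [0.5, 40]
decoding:
  pairs:
    - [hands, animals]
    - [tools, animals]
  cross:
    - {train: [tools, animals], test: hands}
  tg:
    - {train: [tools, animals], test: hands}
  k: 10
  n_repetitions: 3
stats:
  n_perm: 50
  paired:
    - [[hands, animals], [tools, animals]]
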