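# Default pipeline configuration (all values mirror the built-in defaults).
# Stage parameter blocks are passed to the corresponding fit/simulation calls.
out_dir: esmdyn_out
seed: 0
stages: [simulate, gtheory, lmm, ctssm, cthmm, power]
# esm_csv: path/to/esm_data.csv      # load instead of simulating
# item_csv: path/to/item_data.csv
design:
  n_subjects: 80
  n_days: 14
  beeps_per_day: 4
  compliance: 0.768
  time_jitter_sd: 0.015
lmm: {}
ctssm:
  n_starts: 3
  compute_se: false
cthmm:
  n_starts: 2
  compute_se: false
power:
  n_subjects: 21
  n_assessments: 42
  effect_r: 0.1
  alpha: 0.05
  reps: 1000
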