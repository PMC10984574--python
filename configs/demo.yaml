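# Desk-scale demonstration pipeline: a small synthetic cohort with the
# study-scale analysis settings (85th percentile, theta band, five-block
# behavioural units). Null ensembles are reduced from 2000 to 200
# replicates to keep the demo fast; see configs/study.yaml for the full
# study conditions.
seed: 1
null_reps: 200
bands:
  - {name: theta, lo: 4, hi: 7}
simulation:
  design: {n_blocks: 20}
  gts: {n_subjects: 6, n_medicated: 3}
  hc: {n_subjects: 6, acc_learning_pp_mean: 0.7, rt_learning_ms_mean: 8.0, rewire_p: 0.3}
  n_channels: 32
  resting_segments: 20
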