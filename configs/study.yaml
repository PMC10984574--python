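# Full study conditions: 25 participants per group, 20-block cued ASRT,
# 60-channel 500 Hz recordings with 60 resting segments of 2000 ms per
# run, four analysis bands, 85th-percentile thresholding and
# 2000-replicate null ensembles. A complete run is compute-heavy; use
# configs/demo.yaml for a quick look.
seed: 0
null_reps: 2000
simulation:
  design: {n_blocks: 20}
  gts: {n_subjects: 25, n_medicated: 13, acc_learning_pp_mean: 2.0, rewire_p: 0.1}
  hc: {n_subjects: 25, acc_learning_pp_mean: 0.7, rt_learning_ms_mean: 8.0, rewire_p: 0.3}
  n_channels: 60
  resting_segments: 60
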