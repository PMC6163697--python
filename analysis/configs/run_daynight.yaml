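# Full-pipeline RunConfig for `elf-expochar run --config ...`
out_dir: results/run_daynight
seed: 1
cohort:
  n_subjects: 20
  seed: 1
  alarm_clock_prob: 0.0
segmentation:
  penalty: null        # null -> 3*log(n) per day
  min_seg_len: 4
comparison:
  m: 100               # events subsampled per pool and repetition
  reps: 300
  B: 199               # permutations per subsampled test
  standardize: true
  fdr_lambda: 0.5
  fdr_threshold: 0.05
compare_dimensions: [daynight]
min_pool: 20
make_plots: false
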