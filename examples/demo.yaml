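# 12-case / 6-reader demo: completes end to end in ~1 minute on one CPU.
outdir: runs/demo
synthetic:
  n_normal: 9
  n_cancer: 3
  image_size: 128
  n_readers: 6
  error_link_slope: 5.0
  seed: 3
bases: [FP]
roi_kinds: [square]
normalized_tracks: [true, false]
grid:
  n_trees: [100]
  max_sample_fraction: [1.0]
  max_depth: [5]
  n_selected_features: [16]
n_boot: 500
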