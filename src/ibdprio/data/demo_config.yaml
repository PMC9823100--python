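# Default demo configuration: a scaled genome (6 x 150 Mb autosomes + X)
# so the full simulate -> detect -> intersect -> prioritize -> classify
# chain runs in seconds. See data/fullscale_config.yaml for hg19-like scale.
seed: 1
genome:
  n_autosomes: 6
  autosome_mb: 150.0
  x_mb: 155.0
  markers_per_mb: 50.0
  cm_per_mb: 1.0
  maf: [uniform, 0.05, 0.5]
simulate:
  error_rate: 0.002
  missing_rate: 0.002
detector:
  window: 100
  ibs0_tol: 1
  ibd2_tol: 5
  min_length_mb: 5.0
  x_min_length_mb: 10.0
  min_markers: 100
filters:
  af_threshold: 0.01
  af_policy: overall
odds:
  prior: 0.10
  rounded: true
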