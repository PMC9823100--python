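# hg19-like scale: 22 autosomes + X at 1 marker / 10 kb. Slower; not used by
# the test suite. The genome block below approximates hg19 with equal-length
# autosomes summing to ~2.88 Gb; for exact hg19-like lengths use
# ibdprio.genome.default_genome() from Python.
seed: 1
genome:
  n_autosomes: 22
  autosome_mb: 131.0
  x_mb: 155.0
  markers_per_mb: 100.0
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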