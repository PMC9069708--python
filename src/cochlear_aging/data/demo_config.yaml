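# Demo pipeline configuration: every stage on small synthetic inputs.
seed: 1
stages: [expression, deg, genesets, nlc, stiffness, cytology]
thresholds:
  background_rpkm: 0.1
  log2fc_min: 1.0
  fdr_max: 0.10
design:
  n_genes: 1000
  n_replicates_per_group: 3
  frac_up: 0.10
  frac_down: 0.20
  effect_log2fc: 2.0
  nb_dispersion: 0.05
protocol:
  f1: 390.6
  f2: 781.2
  amplitude: 10.0
  dc_levels: [-140, -120, -100, -90, -80, -70, -60, -50, -40, -20, 0, 20, 40, 60]
circuit:
  rs: 10.0
  rm: 500.0
  clin: 7.0
boltzmann:
  qmax: 800.0
  alpha: 33.0
  vpk: -70.0
nlc_noise_rms_pA: 5.0
fiber:
  kf: 2.0
  true_kc: 2.0
  Lf_amp: 50.0
  drive_freq: 100.0
  noise_rms: 1.0
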