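# Bundled synthetic demo: 60 genes, 25 regulated, noiseless replicates.
simulate:
  seed: 42
  n_genes: 60
  n_up: 20
  n_down: 5
  replicate_sd: 0.0
  n_intragenic_unique: 10
params:
  upstream_bp: 2000
  downstream_bp: 1000
  tata_window_up: 150
  tata_window_down: 50
  tata_cutoff: 0.9
  fc_threshold: 2.0
  alpha: 0.05
  test: student
  min_extension_bp: 200
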