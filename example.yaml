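# Worked-example configuration for `bedmr run` (see README).
seed: 7
n_rand: 500
sim:
  n_samples: 30
  n_normals: 5
  n_chroms: 2
  chrom_length: 50000000
  background_bp_rate: 0.5
  n_hotspots: 3
  hotspot_sd: 200000.0
  hotspot_weight: 0.7
  dmr_fraction: 0.1
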