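# Toy study-area scenario shared by the numbered analysis scripts.
# Stages write their artifacts under output_dir; rerunning with the same
# seed reproduces every file byte-for-byte (see results/<scenario>/checksums.csv).
scenario: toy
seed: 7
output_dir: results/toy
synthetic:
  grid_shape: [60, 80]
  cell_area_ha: 900.0          # 3 km x 3 km cells -> province-scale extent
  years: [1995, 2000, 2005, 2010, 2015, 2018]
  autocorrelation_scale: 4.0
  area_noise_sd: 0.005
  change_fraction: 0.03
ca:
  neighborhood_size: 3
  max_iterations: 60
ann:
  hidden_units: 12
  epochs: 300
  sample_fraction: 0.02
demand:
  horizon: 2
esv:
  unit_divisor: 1.0e7
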