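# Small self-contained demonstration run: two biomes, four models.
outdir: pipeline_out
seed: 0
n_pixels: 16
year_start: 2001
year_end: 2004
biome_mix:
  deciduous_broadleaf_forest: 0.5
  grassland: 0.5
gradient:
  mean_annual_temp: [2.0, 10.0]
  seasonal_amplitude: 12.0
  temp_noise_sd: 1.0
  annual_precip: 500.0
  wet_season_center_doy: [170, 230]
  precip_concentration: 2.0
truth_model: gdd
obs_noise_sd: 3.0
models: [gdd, bbgc, ngd, ncd_gdd]
penalty_days: 60.0
# coarse grids keep the demo quick; recovery experiments use the defaults
grid_points:
  t_base: 11
  gdd_crit: 16
  ngd_crit: 20
  a: 7
  b: 7
  c: 5
  d: 7
  k: 7
  g: 5
  h: 5
  w: 5
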