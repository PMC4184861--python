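# Calibrated Northern Hemisphere parameter values for the four onset
# models, one row per vegetation class.
#   gdd:     t_base (degC), gdd_crit (degree-days)
#   bbgc:    t_base (degC); woody classes: a, b (critical sum exp(a + b*T_avg));
#            grass classes: c, d (thermal sum c*max(T_avg,0)+d), k (precip fraction)
#   ngd:     t_base (degC), ngd_crit (days)
#   ncd_gdd: t_chill (degC), t_base (degC), g, h (degree-days), w (per chill day)
evergreen_needleleaf_forest:
  gdd:     {t_base: 6, gdd_crit: 50}
  bbgc:    {t_base: 0, a: 4.755, b: 0.117}
  ngd:     {t_base: 9, ngd_crit: 5}
  ncd_gdd: {t_chill: 0, t_base: 3, g: -300, h: 400, w: -0.1}
deciduous_needleleaf_forest:
  gdd:     {t_base: 2, gdd_crit: 52}
  bbgc:    {t_base: 0, a: 4.755, b: 0.117}
  ngd:     {t_base: 5, ngd_crit: 6}
  ncd_gdd: {t_chill: 0, t_base: -1, g: -300, h: 400, w: -0.1}
deciduous_broadleaf_forest:
  gdd:     {t_base: -5, gdd_crit: 591}
  bbgc:    {t_base: -5, a: 5.505, b: 0.085}
  ngd:     {t_base: 6, ngd_crit: 21}
  ncd_gdd: {t_chill: 0, t_base: -5, g: -100, h: 700, w: -0.1}
cool_mixed_forest:
  gdd:     {t_base: 5, gdd_crit: 52}
  bbgc:    {t_base: 0, a: 4.63, b: 0.101}
  ngd:     {t_base: 8, ngd_crit: 6}
  ncd_gdd: {t_chill: -5, t_base: 3, g: -300, h: 400, w: -0.1}
warm_mixed_forest:
  gdd:     {t_base: 7, gdd_crit: 236}
  bbgc:    {t_base: -5, a: 6.005, b: 0.057}
  ngd:     {t_base: 5, ngd_crit: 59}
  ncd_gdd: {t_chill: -5, t_base: 5, g: -300, h: 600, w: -0.1}
cool_closed_shrub:
  gdd:     {t_base: 5, gdd_crit: 50}
  bbgc:    {t_base: 2, a: 4.13, b: 0.109}
  ngd:     {t_base: 8, ngd_crit: 5}
  ncd_gdd: {t_chill: -5, t_base: 3, g: -300, h: 400, w: -0.1}
warm_closed_shrub:
  gdd:     {t_base: 7, gdd_crit: 308}
  bbgc:    {t_base: -5, a: 6.63, b: 0.041}
  ngd:     {t_base: 5, ngd_crit: 77}
  ncd_gdd: {t_chill: -5, t_base: 5, g: -300, h: 700, w: -0.1}
cool_open_shrub:
  gdd:     {t_base: 0, gdd_crit: 140}
  bbgc:    {t_base: -3, a: 5.505, b: 0.057}
  ngd:     {t_base: 5, ngd_crit: 11}
  ncd_gdd: {t_chill: -5, t_base: 1, g: -300, h: 400, w: -0.1}
warm_open_shrub:
  gdd:     {t_base: 7, gdd_crit: 350}
  bbgc:    {t_base: -5, a: 6.005, b: 0.069}
  ngd:     {t_base: 10, ngd_crit: 41}
  ncd_gdd: {t_chill: -2, t_base: 7, g: -300, h: 600, w: -0.1}
cool_woody_savanna:
  gdd:     {t_base: 3, gdd_crit: 58}
  bbgc:    {t_base: 0, c: 15, d: 119, k: 0.05}
  ngd:     {t_base: 7, ngd_crit: 6}
  ncd_gdd: {t_chill: -5, t_base: 1, g: -300, h: 400, w: -0.1}
warm_woody_savanna:
  gdd:     {t_base: 7, gdd_crit: 296}
  bbgc:    {t_base: -5, c: 5, d: 119, k: 0.06}
  ngd:     {t_base: 5, ngd_crit: 58}
  ncd_gdd: {t_chill: -5, t_base: 5, g: -300, h: 600, w: -0.1}
savanna:
  gdd:     {t_base: 1, gdd_crit: 126}
  bbgc:    {t_base: -2, c: 11, d: 209, k: 0.16}
  ngd:     {t_base: 5, ngd_crit: 12}
  ncd_gdd: {t_chill: -5, t_base: 5, g: -300, h: 400, w: -0.1}
grassland:
  gdd:     {t_base: -5, gdd_crit: 448}
  bbgc:    {t_base: -5, c: 15, d: 369, k: 0.05}
  ngd:     {t_base: 6, ngd_crit: 12}
  ncd_gdd: {t_chill: -5, t_base: 5, g: -300, h: 400, w: -0.1}
permanent_wetland:
  gdd:     {t_base: -5, gdd_crit: 378}
  bbgc:    {t_base: -1, a: 5.005, b: 0.101}
  ngd:     {t_base: -4, ngd_crit: 47}
  ncd_gdd: {t_chill: -5, t_base: 1, g: -300, h: 400, w: -0.1}
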