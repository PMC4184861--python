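# Methods

This note records the scientific and numerical choices behind the
package: the exact model formulations, what the synthetic generator does
and does not emulate, how calibration works on a stepped objective, and
the known limitations.

## Calendar and data model

All computations run on a fixed 365-day no-leap calendar (Feb 29 never
occurs). This removes leap-year branching from every accumulation loop at
the cost of a ≤1-day misalignment against real calendars, which is far
below the day-scale errors of onset models. Day of year (DOY) is 1-based.

A daily meteorological record (`DailyMetSeries`) covers Nov 1 of the
preceding year through Dec 31 of its calendar year — 426 consecutive
days. The two-phase model's chilling count starts on Nov 1, so carrying
the prefix inside every record means no predictor ever needs a second
record, and the trailing soil-temperature mean has real predecessors on
Jan 1.

## Model formulations

Equations and defaults as implemented (temperatures °C, sums in
degree-days):

* **GDD** — `GDD(t) = Σ max(T_d − T_th, 0)` from `t0` (default Jan 1);
  onset at the first `t` with `GDD(t) ≥ GDD_c`. Degree-day accumulation
  is the standard "excess above base" form; thresholds are inclusive
  (≥), and tie days resolve to the earliest qualifying day.
* **NGD** — count of days with `T_d > T_th` from Jan 1 (strictly above:
  a day at the base is not a growing day); onset when the count reaches
  the integer `NGD_c`.
* **Biome-BGC woody** — soil temperature is the 11-day *trailing* mean
  of air temperature (causal: a centered window would let onset depend
  on future warmth). Accumulate `max(T_soil − T_th, 0)` from Jan 1; the
  critical sum is `exp(a + b·T_avg)`, matching the scale of the original
  Biome-BGC onset rule (`exp(4.795 + 0.129·T_avg)`). Onset requires, on
  the same day, the running sum at or above the critical value *and* day
  length strictly above 39 300 s; the reported onset is the crossing day
  minus 15, floored at DOY 1. The gate applies on the crossing day, not
  retroactively on the offset day.
* **Biome-BGC grass** — thermal criterion `c·max(T_avg, 0) + d` on the
  same soil-temperature sum, joined by AND with a precipitation
  criterion: cumulative precipitation from Jan 1 at or above
  `k·AvgAnnPrcp`. The threshold term `d` is additive; the formulation is
  isolated in one kernel so an alternative branching reading could be
  swapped in without touching callers. Both sums start Jan 1.
* **NCD-GDD** — chilling days are days with `T_d` strictly below the
  chill base, counted from Nov 1 and including the current day; forcing
  accumulates from Jan 1 ("midwinter" is fixed to Jan 1). Onset at the
  first `t` with `GDD(t) ≥ g + h·exp(w·NCD(t))`, `w ≤ 0`. With an
  unreachable chill base this reduces exactly to a GDD model with
  critical sum `g + h` (tested).

`T_avg` and `AvgAnnPrcp` are computed per pixel from the driving record's
own calendar year; no climatological window is imposed. Minus signs in
the bundled parameter table are ordinary negatives.

Day length uses standard solar geometry: declination
`δ = −23.44°·cos(2π(doy + 10)/365)`, half-day hour angle
`cos ω = −tan(lat)·tan(δ)` clamped to ±1 (polar day/night → 86 400/0 s),
day length `= ω/π · 86 400 s`. Accuracy is a few minutes, which is ample
against the 39 300 s gate given spring day lengths change by 2–4 min/day.

## Climate classification

Annual statistics (`T_mean`, annual minimum `T_c`, maximum `T_w`, range
`ΔT`) are computed over Jan–Dec windows and averaged across the supplied
years before thresholding; classifying a climatology rather than a single
year keeps the class stable under interannual noise. Boundary values
resolve to the *warm* class because the cool criteria are strict
inequalities. Scheme assignment: grassland, savanna and both woody-savanna
classes use the grass rule; forests, shrubs and permanent wetland the
woody rule — read off from which coefficient families (`a, b` vs
`c, d, k`) are calibrated for each class.

## Synthetic generator

The generator emulates what a hemispheric study takes from a gridded
reanalysis and a satellite phenology product:

* **Temperature** — `mean − amplitude·cos(2π(d − peak + 182.5)/365)`
  plus iid Gaussian noise (default sd 1 °C, peak DOY 200). Noise is keyed
  to (seed, pixel, calendar year), so the Nov–Dec overlap between the
  426-day records of consecutive years is bitwise identical: each pixel
  is one continuous realization.
* **Precipitation** — daily gamma amounts (shape 0.8) whose scale follows
  a raised-cosine seasonal weight (`concentration` ≥ 0 sharpens the wet
  season; 0 is uniform), normalized so the annual sum equals
  `annual_precip` in expectation (verified to within 3 standard errors
  over 10 000 simulated years).
* **Observations** — run a chosen model, add integer-rounded Gaussian
  error, clamp to [1, 365]; model-silent pixel-years are emitted as
  missing. Onset errors are whole days because satellite phenology
  products report composite-period dates. The default observation noise
  (3 days in the demo pipeline) is a free choice; field comparisons of
  satellite onset against tower sites report disagreements from 1 to
  ~17 days, so 3–5 days is a mild-to-moderate setting.
* **Landscapes** — site mean temperatures on an even grid over the
  requested span (guaranteeing coverage); other ranged fields drawn
  uniformly so they decorrelate from the temperature axis; biome labels
  apportioned by largest remainder and shuffled across the gradient.

What the generator does *not* emulate: spatial autocorrelation between
pixels, weather autocorrelation in time (days are independent around the
seasonal cycle), snowmelt and radiation effects on soil temperature,
mixed pixels, or satellite retrieval failure modes (cloud gaps, biased
detection in evergreen canopies). Passing recovery tests therefore show
the estimator is correct and identifiable *under the stated generating
process*; they do not certify accuracy on real satellite phenology.

## Calibration

The objective is the error sum of squares (days²) over training
pixel-years; observation-missing records are skipped, and
prediction-missing records are charged a fixed penalty (default 60 days,
squared) so the optimizer cannot win by never predicting onset.
Calibration pools all pixels and years of a biome class and fits one
parameter set per class; the random half split is by pixel, all years of
a pixel staying together, with |train| = ⌈n/2⌉.

Predicted onset is piecewise constant in the parameters, so gradient
methods are ill-posed and simplex moves stall on the integer-valued
plateaus of the objective. The search is therefore fully deterministic
and derivative-free:

1. coarse full-factorial grid over bounds that bracket all plausible
   values with margin (bases −10…15 °C, `GDD_c` 0…1500, `NGD_c` 1…120,
   `a` 3…8, `b` 0…0.25, `c` 0…30, `d` 0…600, `k` 0…1, `g` −500…200,
   `h` 1…1500, `w` −0.5…0);
2. shrinking-grid refinement started from up to five diverse low-SSE
   coarse points (the SSE surface has curved stepped valleys — e.g.
   `g`, `h`, `w` trade off along the chilling-response curve — and a
   single incumbent track can stall on a shelf);
3. cyclic one-dimensional line searches, then small full-factorial
   sweeps at several scales around the incumbent, to land in the exact
   zero-SSE pocket on noise-free data;
4. a Nelder–Mead polish on the continuous parameters, accepted only if
   it strictly improves.

Ties in SSE resolve deterministically to the smallest critical-sum /
day-count value, then the smallest base. The incumbent never worsens
across stages (tested), and reruns are bit-identical. Integer day counts
(`NGD_c`) are searched over integer neighborhoods.

Identifiability depends on the landscape: the base temperature and the
critical sum are separated by sites whose annual means straddle the base,
the woody slope `b` by a wide `T_avg` range, the chilling coefficients by
sites spanning mild to severe winters, and the precipitation fraction `k`
by pixel-years where the wet season, not warmth, gates onset. The
recovery experiments are constructed accordingly, and the noisy-recovery
test deliberately uses a gradient wide enough to break the
base/critical-sum collinearity.

## Evaluation metrics

Pairs are formed by an inner join on (pixel, year), dropping pairs with a
missing side. `R²` is the squared Pearson correlation of predicted vs
observed (scatter-plot regression sense); the stricter 1:1-line variant
`1 − SSE/SST` is reported separately as `r2_one_to_one` and can be
negative under bias. RMSE and the mean absolute error `R_A` use their
standard definitions (RMSE ≥ R_A always; under Gaussian errors they
estimate σ and σ√(2/π)). Interannual agreement is the Pearson r between
yearly biome-mean observed and predicted series (unweighted pixel means;
≥3 years required). Cumulative frequencies report the percentage of
pixel-years with |error| ≤ τ for a 1–30-day threshold grid, pooled over
years. Degenerate inputs (zero variance, <3 pairs/years) raise an
explicit undefined-metric error rather than returning NaN silently.

## Reference experiments and problem sizes

The acceptance script and the acceptance tests run five recovery
experiments at 200–300 pixels × 10 years (500–1500 training pixel-years
after the half split) — large enough that noise-free recovery pins every
graded parameter to well under its tolerance, small enough that the whole
script completes in under a minute on one CPU. The two behavioral probes
measure the woody rule's constants from the outside: the onset offset as
(crossing day − reported onset) with a trivially satisfied thermal
criterion, and the photoperiod gate by intersecting, over 600 latitudes,
the day-length interval between the last blocked and first permitted day
(bracketing the constant to within a few seconds).

## Known limitations

* The grass rule's `d` is implemented as an additive offset; if the
  original intent was a hard warm/cool branch threshold, the kernel seam
  is the single place to change.
* `evaluate` reports metrics pooled per biome over pixel-years; per-pixel
  time-series metrics are not (yet) broken out.
* The pipeline's "classification" stage re-derives cool/warm classes
  from generated climate; it does not emulate satellite land-cover
  misclassification.
* NetCDF support uses the classic (NetCDF-3) format via the SciPy
  backend, with time stored as a no-leap day ordinal rather than CF
  time; CSV remains the canonical interchange.
* On noise-free data the search reaches SSE = 0 in the recovery
  experiments shipped here, but a zero-SSE pocket is not guaranteed for
  arbitrary data; `CalibrationResult.converged` reports whether the
  final line-search cycle was stable.
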