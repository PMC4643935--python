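# Methods

## The analysis chain

The pipeline reproduces a standard grazing–stream-temperature study
design on three subalpine meadow streams: one meadow partially grazed
(a livestock exclosure since 1991 splits it into a grazed upstream reach
and an ungrazed downstream reach) and two meadows rested since 2001.
Temperature loggers (±0.2 °C instrument class) sample every 20–30 minutes;
analysis is restricted to the eight warmest weeks of each year.

**Metrics.** Per probe and calendar day: DminT, DavgT, DmaxT. The
"weekly" metrics WminT/WavgT/WmaxT are centred 7-day moving *medians* of
the daily values — the median is used so a single aberrant day (a probe
briefly out of the water, an electronic glitch) cannot drag the weekly
value. Season maxima MWavgT = max WavgT and MWmaxT = max WmaxT summarise
chronic and acute exposure: they are the average and maximum daily values
during the warmest consecutive seven days.

**Autocorrelation.** Thermal data are autocorrelated in time (measurements
minutes apart), in space (probes along one channel) and by repetition
(each probe measured daily). Ignoring this inflates t and F statistics
without biasing the effect sizes. The package addresses each source the
way the field does: temporal autocorrelation by aggregating to weekly /
monthly / yearly means before testing (all three scales are reported,
exposing the power-vs-calibration trade-off); spatial structure by
entering coordinates and their squares as covariates where it is
detected; repeated measures by random intercepts. Moran's *I* with
inverse-distance weights (great-circle metres for coordinates, absolute
lags for time) is attached to every model's residuals as a diagnostic;
its null moments follow the randomization assumption
(E[*I*] = −1/(n−1), Cliff–Ord variance, two-sided normal p; a seeded
permutation option exists for small n).

**Mixed models.** Group contrasts use
`metric ~ reach + (1 | time unit) [+ (1 | probe)]`; the projection model is
`DmaxT ~ WavgT + (1 | date)` per meadow, plus one all-meadow fit with a
meadow × WavgT interaction for slope contrasts. Fitting is REML with the
variance ratios profiled out (Woodbury identities, so cost scales with
random-effect levels, not observations). Contrast degrees of freedom use
the Satterthwaite approximation (delta method on the finite-difference
REML information); on balanced designs this reproduces the classical df
exactly (tested against the two-sample t-test and against lmerTest-style
references via statsmodels cross-checks).

**Projection.** Air-warming scenarios (0, 1, 3.7, 5.6 °C) scale to water
by a fixed conservative ratio of 0.5 °C/°C; the printed water deltas
(0, 0.5, 1.8, 2.8) are used as given rather than recomputing 3.7 × 0.5.
Expected DmaxT = intercept + slope × (baseline WavgT + Δwater). Bands are
normal quantiles at 50/95/99 % two-sided coverage with
sd_total = √(residual σ² + date-intercept τ²) by default
(`residual_only` available); their upper limits are labelled 2-, 20- and
100-year recurrence temperatures — the upper limit of a two-sided 95 %
band is strictly a 2.5 % exceedance, but the recurrence labels follow the
field convention deliberately. Band widths are scenario-invariant and the
expectation is affine in Δwater with the fitted slope; both are asserted
on every report row.

## The synthetic generator

No logger data were deposited, so every downstream stage is exercised on
synthetic studies whose defaults *are* the study conditions: reaches of
17/13/30/21 probes over 900/1200/1500/1200 m, weeks 24–31 of 2010–2012,
30-minute sampling.

The daily mean at probe *p*, day *d* is

    m(p, d) = baseline(reach) + (g/s) · distance(p)/100 m
            + seasonal(d) + weather(week(d)) + offset(p)

with a half-sine seasonal anomaly (amplitude 2.5 °C, centred to zero mean
over the simulated days, peak near week 28), a regionally shared weekly
AR(1) "weather" anomaly (sd 0.8 °C, φ_week 0.6 — shared across meadows
because they sit within ~10 km on one plateau, which is also what the
comparison model's common month random intercept presumes), and a
persistent per-probe microhabitat offset (sd 0.8 °C) that gives the
season-maximum regressions their realistic residual scatter (per-fit SE
≈ 0.13 °C/100 m on 17 probes). On this rides a diel sinusoid peaking at
16:00 whose base amplitude depends on solar exposure (sunny ≥ 98 %:
5.4/4.3/5.8 °C by meadow; shaded: 2 °C less), plus stationary AR(1)
logger noise (marginal sd 0.8 °C, φ = 0.9 per 30-min step — water has
strong thermal inertia) whose cross-probe correlation decays as
exp(−d/25 m) along the stream (weak at the ~60 m probe spacing, matching
the near-null residual Moran's *I* the gradient fits should show).

Two couplings make the nominal parameters *observable*:

* `gradient_per_100m` is the trend of the **daily maximum** (the quantity
  the gradient analysis reports); the daily-mean trend is g/s. The
  zero-noise contract is exact: two probes 100 m apart differ by exactly
  0.41 °C in every daily maximum.
* the diel amplitude is modulated by the realized 7-day-median smoothed
  daily mean (i.e. the quantity the pipeline measures as WavgT), so
  DmaxT = const + s · WavgT holds *at the scale the projection model fits
  it*, with `max_vs_avg_slope` s = 1.74/1.62/1.48 by meadow. Monte-Carlo
  checks (200 replicates) show both the gradient and the slope recovered
  without detectable bias (gradient mean 0.40–0.41 vs nominal 0.41;
  slope mean 1.7398 vs nominal 1.74).

Reach baselines (12.1/13.9/11.8/10.7 °C at the upstream probe) are chosen
so realized reach means land on the observed summer summaries
(≈ 13.2/13.0/11.8/10.7 °C). The willow census uses exact observed counts
by default (980 stems/1200 m ungrazed, 75/900 m grazed; truncated-normal
heights 92 ± 56 vs 43 ± 29 cm, floor 1 cm); Poisson-by-density mode
exists. Out-of-water injection replaces listed days with air-like swings
(≥ 2.5× the clean diel range) and flags them.

Randomness is keyed hierarchically off one root seed (stable CRC32 hashes
of probe ids and stream names), so meadows never share streams and
identical configurations are bit-reproducible. Within a meadow the exact
exponential spatial kernel requires joint Cholesky mixing, so inserting a
probe does perturb its meadow's noise — kernel fidelity was chosen over
insertion invariance.

**What the generator does not emulate:** asymmetric diel curves (real
streams warm slower than they cool, so synthetic WminT sits lower than
field summaries), tributary and groundwater inputs, diurnal cloud
forcing, sensor drift, and willow spatial clustering (the field spacing
statistics imply clustered stems; the generator matches counts, not
clustering). Passing recovery tests therefore show the *estimators* are
calibrated for data with the assumed structure, not that real meadow
streams satisfy that structure.

## Calibration experiments and their design

* **Gradient recovery** (100 fixed-seed replicates of a 17-probe grazed
  reach, one summer): mean estimate within 2 reported SEs of 0.41; 95 %
  t-intervals required to cover in ≥ 90/100 replicates. The 90 threshold
  is deliberate: a perfectly calibrated 95 % interval fails "≥ 95 of 100"
  about half the time by binomial noise, while P(< 90 | true 95 %) ≈ 1 %.
  Null reaches (gradient 0) must reject at ~5 % (accepted band
  0.005–0.12 over 100 replicates).
* **Type-I calibration** (200 fixed seeds): null weekly metric values per
  group as AR(1) with φ = 0.5, three years of eight weeks, months built
  as two balanced 4-week blocks (the 8-week summer window contains no
  complete calendar month). Month-scale rejection stays within
  [0.01, 0.10] (measured 0.07); week-scale inflates to ~0.26 — the
  trade-off that motivates monthly averaging.
* **Recovery checks that average over replicate studies** use 2 simulation
  standard errors of the replicate mean. Single-fit SEs from the mixed
  model understate between-replicate scatter (weather and probe-offset
  realizations act as cluster effects), so they are not used as recovery
  bands.

## Numerical choices

* Week-of-year: ISO-8601 (`ordinal` = ceil(day-of-year/7) available);
  timestamps are naive local clock time, day boundary at 00:00.
* Day completeness: a day needs ≥ 75 % of expected records
  (1440/interval) to enter the weekly metrics.
* Moving window: centred, 7 days, ≥ 4 valid days (`trailing` available);
  even-count medians are the mean of the central pair; calendar gaps count
  as missing days, so windows never bridge the between-summer gap.
* Season maxima are study-duration maxima (per-year mode available; their
  across-year maximum is identical).
* Coincident points in inverse-distance weights are floored at half the
  smallest positive distance; all-coincident input is an error, as are
  constant residuals in Moran's *I*.
* Variance ratios are optimized on the log scale in [e⁻¹⁶, e⁸] by
  Nelder–Mead from a coarse grid; ratios below 1e−5 are pinned to zero
  and flagged (`singular`), as are exact-fit responses (residual sd
  < 1e−6). Satterthwaite df are clipped to [1, n−p] with a residual-df
  fallback when the information matrix is not invertible.
* Rendered report tables round half-up to 1 decimal; machine CSVs keep
  full precision.
* The two areas of the partially grazed meadow are pooled for projection
  baselines by default (grazed-only mode available); contrasts are
  reported unadjusted for multiple testing, as is conventional for this
  design (a Holm option exists in the API surface via post-processing).

## Known limitations

* The generator's WminT structure is symmetric with WmaxT, so minimum-
  temperature contrasts are less faithful to field summaries than the
  mean/maximum ones.
* The vegetation-class test on 30 probes has modest power; single
  synthetic studies often return a non-significant chi-squared even
  though the class probabilities differ by treatment.
* Sub-daily noise interacts with maximum-selection: with fast
  (low-persistence) noise the season-maximum estimator acquires a small
  amplitude-dependent bias. The default φ = 0.9 keeps this negligible;
  users lowering φ far below ~0.7 should re-check gradient calibration.
* The projection bands describe across-day/across-site normal spread
  around the fitted line; they are not an extreme-value model, and the
  recurrence labels inherit the field's convention rather than a formal
  return-period analysis.
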