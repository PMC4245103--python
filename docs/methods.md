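# Methods

## The problem

Archival time-depth-light recorders (TDLRs) carried by southern elephant
seals sample depth, ambient blue light and temperature every 30 s for
months at sea.  In Case-1 waters — where phytoplankton and covarying
material dominate optical attenuation — the rate at which downwelling
light decays with depth indexes phytoplankton density.  This package
implements the full chain from raw tag records to a daily, position-
matched phytoplankton index and its calibration against satellite
chlorophyll-a:

1. zero-offset correction of the pressure record and segmentation into
   dive cycles;
2. per-dive water-column structure (broken-stick inflections of
   temperature and light profiles, T200, frontal zone);
3. the integrated light-attenuation index
   `LA250 = (LL_0 − LL_250) / 250 m` from local-noon dives;
4. 1° × 8-day × seal gridding against satellite chlorophyll composites
   with ice, profile-count, season and latitude-band filters;
5. AIC-ranked selection among 16 log-log linear mixed-effects models and
   a REML refit of the winner.

A synthetic-data generator with planted ground truth makes every stage
testable without a real deployment.

## Sensor model

The logger compresses light intensity `I` (W cm⁻²) to a relative level

    level = 150 + 20 · log10(I / 1e−5),

clamped to [0, 250] and rounded to the nearest integer (20 levels per
decade, so the quantization error is 1/20 of a decade, at most 0.5
levels).  The manufacturer's check intensities 1e−5, 1e−7 and 1e−9
W cm⁻² map to levels 150, 110 and 70.  Because the scale is log-linear,
exponential decay `I(z) = I₀ e^(−kz)` appears as a straight level-depth
line with slope `20 k / ln 10` levels per metre, and

    LA250 = (20 / ln 10) · K̄,

where `K̄` is the mean diffuse attenuation coefficient over the top
250 m.  LA250 is invariant to surface irradiance and to any per-tag
sensitivity offset, since both shift `LL_0` and `LL_250` equally.

Clock drift of the uncorrected watch crystals follows
`TE = (1e−5 − 3.5e−8 (T − 25)²) · 1e6` µs per second at water
temperature `T`; the generator can apply it, and `clock_time_error`
evaluates it exactly.  A first-order sensor-lag correction
(`y_true = y + τ·dy/dt`) is provided but off by default: the pipeline
controls the light sensor's response lag by averaging descent and ascent
phases instead, which is why a light-inflection depth is only reported
when both phases yield one.

## Dive processing

**Zero-offset correction.** Pressure sensors drift by metres over a
trip.  The offset is tracked in 1-h blocks as the mode (0.5-m bins,
lower bin edge) of readings shallower than 15 m within a centred 6-h
rolling window; blocks with no shallow readings carry the previous
offset forward, corrected depths are clamped at 0.  The lower-edge
convention makes an already-correct series a fixed point; exact
bin-count ties take the median tied bin so a slow drift is tracked
without directional lag.  The routine is idempotent to within one bin
and keeps the residual surface error under ~1 m for drifts up to
0.25 m/h.

**Segmentation.** A dive cycle runs from the first record deeper than
10 m to the last record of the following surface interval (0–10 m, a
tolerance for sub-surface swimming between dives).  Records before the
first dive are surface; a deployment ending under water leaves a flagged
incomplete dive.  Record counts are conserved exactly
(dive + surface + incomplete = total), and the implementation is tested
against an explicit per-sample state machine.  Phases split at the first
record attaining maximum depth, which is deterministic for flat-bottomed
dives.

## Water-column structure

The "greatest inflection point" of a profile is the two-segment
piecewise-linear breakpoint minimising total RSS over candidate
breakpoints at every interior observed depth between 15 and 350 m
(the light sensor's working range); ties break shallow.  The
implementation uses cumulative second moments (O(n) over all
candidates) and is property-tested against an exhaustive per-candidate
polyfit search.

The temperature breakpoint is reported as the mixed-layer depth when the
surface temperature (mean of the 8–12 m band) differs from the
breakpoint temperature by more than 0.2 °C.  Note a textbook perfectly
isothermal mixed layer fails this criterion (the breakpoint temperature
*equals* the surface temperature); the criterion is kept literal
because it is the published rule, and a config switch
(`criterion="across_breakpoint"`) compares the temperature just above
the breakpoint with the profile 20 m below it instead, which detects
that case.

T200 interpolates temperature at 200 m linearly within each phase and
averages the phases.  Frontal zones follow subsurface boundaries: PFZ
above 2.8 °C, SACCF-N between 1.6 and 2.8 °C, SACCF-S below 1.6 °C
(boundary values join the colder-side-inclusive zone; the SAF reference
is 7 °C).  Zone assignment uses the mean T200 of local-noon dives only,
matching the index's noon window.

## The LA250 index

`LL_0` is the mean light level of wet records at 0–10 m at the end of
the ascent (dry records, i.e. sensor above the surface, are excluded);
`LL_250` interpolates the level at 250 m, averaging descent and ascent
when both bracket 250 m.  Only dives starting within 1100–1300 local
solar time (UTC + lon/15) contribute, which keeps the ambient light
field nearly stationary over a dive; a seal-day needs ≥ 3 such profiles
to be analysable.  Dives whose 250-m level falls below level 25 are
treated as at the sensor floor and excluded (configurable).  Seal-days
are keyed by local calendar date so the noon window never straddles the
day key near the antimeridian.

## Gridding and the mixed model

Analysable noon estimates are averaged into cells keyed by 1° latitude ×
1° longitude × 8-day composite window (anchored 1 January, half-open
membership) × seal.  The seal key matches the model's random-effect
grouping; the 1° scale absorbs light-geolocation error (~57/54 km).
Cells are excluded for < 3 profiles, > 20 % sea-ice at a member
location, winter, latitude outside 52–64 °S, or a fully cloud-masked
satellite cell; the filter ledger accounts for every cell exactly, with
that fixed precedence.

Both chlorophyll and LA250 enter on the natural-log scale; latitude is
centred at −58° (band midpoint) to stabilise interaction estimates;
season is treatment-coded against autumn (or the first available level
when autumn is absent from a cohort).  The 16 candidate fixed-effect
structures combine LA250, season, latitude and their interactions up to
the three-way term.  Every candidate carries a random intercept by seal
plus a random LA250 slope where LA250 is present; a random-slope fit
that fails to converge to a finite, non-singular optimum at least as
good as its nested random-intercept fit is replaced by the latter and
flagged.  Candidates are fitted by ML (statsmodels `MixedLM`) with warm
starts — the random-intercept model from the OLS solution, the
random-slope model from the intercept optimum — because cold-started
optimizers stall on the nearly flat profiled surface when variance
components sit at the zero boundary; BFGS (L-BFGS for the slope model)
falls back to Powell.  At the zero-variance boundary itself the mixed
model reduces exactly to OLS but its profiled information matrix
degenerates and the reported fixed-effect SEs can fall below the OLS
bound, so degenerate fits take the covariance of the limiting OLS model
(flagged on the fit).  Candidates are ranked by
`AIC = 2k − 2 logLik` with `k` counting fixed effects, random-effect
(co)variances and the residual variance, and the best structure is
refitted by REML for reporting.  Light-based chlorophyll (`TDLR_chl`)
exponentiates fitted values, adding the estimated random effects for
in-sample seals.

## The synthetic ocean

`OceanTruth` is a parametric world with:

* a **near-surface chlorophyll field** — lognormal around a
  seasonal-latitudinal mean: background 0.25 mg m⁻³, a summer bloom of
  log-amplitude 1.2 centred at 62.5 °S (Gaussian width 8°, peaking
  21 January), plus a constant-amplitude tilted plane-wave ripple
  (log-amplitude 0.5) providing strong longitude-resolved variation at
  every latitude — the identifying variation that separates the index
  from the latitude and season covariates.  The field is
  **piecewise-constant over 1° blocks and 8-day composite windows**: the
  planted log-log slope is then exactly the estimand of the gridded
  regression.  Real fields carry sub-grid structure, which acts as
  errors-in-variables on the index side and attenuates the fitted
  coefficient — passing recovery tests here therefore validates the
  estimator under its own resolution, not immunity to sub-grid variance.
* a **surface/column decoupling**: satellites see near-surface
  chlorophyll while the index integrates 250 m.  Their relationship in
  log space is affine, `log chl_surface = a(season, lat) +
  s(season, lat) · log chl_column + const`, with
  - additive offsets `a`: +0.33 summer, +0.21 spring (relative to
    autumn) and −0.06 − 0.03/deg poleward of 58 °S (the ratio grows
    poleward: deep mixing and deep chlorophyll maxima hide column
    biomass from the satellite at high latitude, which also keeps the
    index clear of the sensor's quantization floor across the band);
  - coupling slopes `s = 1 + 0.04·(lat + 58) + 0.30·[summer]`, exactly
    1 at 58 °S outside summer (bloom stratification concentrates
    biomass near the surface, strengthening the coupling in summer and
    equatorward).
  This gives season, latitude, **and their interactions with the index**
  genuine explanatory power in the satellite response, so the candidate
  set is a correctly specified family and AIC selection is driven by
  signal.  Without the additive part, season/latitude would be exactly
  collinear with the index; without the slope part, LA×season and
  LA×latitude candidates could only ever fit noise, and conditioning on
  such spurious selections biases the selected model's LA coefficient
  well beyond its nominal SE (a post-selection-inference failure
  observed empirically).  The reference-condition slope — what the
  centred, treatment-coded mixed model reports as its LA250 main
  effect — is exactly `beta_true`.
* **optics**: `k = k_water + k_chl · chl_column^beta_true` with
  `k_water = 0.016 m⁻¹` (clear water near 430 nm) and
  `k_chl = 0.06 m⁻¹ (mg m⁻³)⁻¹`.  Note non-zero `k_water` dilutes the
  log-log response: the expected fitted coefficient is
  `beta_true · k/(k − k_water)` at typical attenuation (~1.6–1.8 with
  defaults), which the analysis scripts report; parameter-recovery
  experiments set `k_water = 1e−4` so the planted slope is 1.
* **hydrography**: isothermal mixed layer (40–90 m, seasonal) over a
  linear thermocline pinned to a monotone T200-latitude relation
  (2.5 °C at 58 °S, 0.28 °C/deg); a seasonal ice edge (−60° in
  September to −72° in February); a smooth ridge-and-basin bathymetry
  (2.2–4.6 km).

Deployments are symmetric V-dives at 1.5 m s⁻¹ vertical speed to
uniform 150–600 m depths, 60 dives/day in equal slots, with surface
intervals of shallow (0.5–2 m, wet) swimming and 20 % dry records at
0 m.  Surface irradiance is `1e−2 · sin(max(solar elevation, 0))`
W cm⁻², which keeps noon levels inside the sensor's check range down to
~300 m.  Tracks leave Macquarie Island (54.58 °S, 158.97 °E) on a
~12-day directed transit (80–140 km/day, persistent heading) before a
correlated foraging walk (20–90 km/day); all daily displacements stay
below the 150-km plausibility bound.  Chlorophyll by default fills the
column uniformly (so light profiles are log-linear and LA250 has the
closed form above); `chl_vertical="mixed_layer"` confines it above the
mixed layer, planting a light inflection at the MLD.  Samples are
assigned to the *local* calendar day they fall in (UTC + lon/15 h) when
looking up the day's position and ocean state, matching how seal-days
are keyed downstream — east of ~165 °E the final hours of a UTC day
already belong to the next local day, and keying them inconsistently
would mispair local-noon dives with positions and composite windows.
One RNG stream per deployment is keyed by (seed, seal id), so cohorts
are reproducible under parallel generation.

Satellite products: 8-day 0.1° chlorophyll composites with
multiplicative lognormal noise — iid σ = 0.2 per pixel plus a
retrieval-error draw of σ = 0.25 per aligned 1° block per window
(algorithm/atmospheric-correction error is spatially coherent; drawing
it at exactly the analysis-cell scale keeps residuals independent
across cells, which the mixed model assumes — a smooth 2°-correlated
component is available but off by default precisely because it
violates that assumption and invalidates the model's nominal SEs) —
and a cloud mask whose missingness increases poleward and in winter
while averaging the requested fraction (default 0.3).  Daily sea-ice
grids at 25-km class resolution are ≥ 50 % south of the seasonal edge
with a marginal ice zone decaying north of it.

### What the generator does not emulate

No behavioural structure (drift dives, bouts, haul-outs), no ocean
circulation or fronts that move, no sub-grid chlorophyll patchiness, no
DCM vertical structure (the surface/column wedge is statistical, not
mechanistic), no SeaWiFS algorithm biases, no light-sensor temperature
compensation error, and no body-roll shading.  Passing tests therefore
validate the *estimator chain*, not robustness to these real-data
effects.

## Validation experiments

* **Closed-form recovery**: constant-k water, no quantization — every
  local-noon dive's LA250 equals `(20/ln 10)·k` within 0.004 levels/m
  (one quantization step over 250 m; the residual is the ~1-m surface
  measurement depth of LL_0 and the ZOC shift).  Away from noon the
  ambient field drifts during a dive and LL_0/LL_250 are not
  concurrent, which is the reason the estimator itself is
  noon-restricted.
* **Oracle equivalence**: segmentation and broken-stick match
  brute-force references on 500 random instances each.
* **Parameter recovery**: 20 seals × 90 days (staggered 3 days apart
  from 1 October, keeping the whole cohort in well-populated spring and
  summer), `k_water = 1e−4`, full pipeline; the selected model's LA250
  coefficient covers the planted unit slope within 2 SE in ≥ 93 of 100
  seeded replicates.  The experiment is sensitive to design details
  that break the mixed model's assumptions — shared satellite scenes
  across seals (hence the stagger and transit), scarce season reference
  levels, degenerate variance components (hence the OLS-limit
  covariance below), antimeridian day-keying consistency, and response
  structure either collinear with the index or carrying no real
  interaction signal for the selection to find (hence the two parts of
  the surface/column decoupling) — documented here because those are
  exactly the caveats that apply to the real-data analogue.

## Numerical choices and conventions

* Half-open cell membership `[edge, edge + step)` on both grid axes;
  8-day windows anchored 1 January, truncated at year end.
* Broken-stick ties break shallow; ZOC mode ties take the median tied
  bin; both for determinism.
* Frontal-zone boundary temperatures join the colder-side zone.
* The noon window is closed, [11.0, 13.0] local solar hours, applied to
  the dive start time.
* Logs are natural logs throughout the model.
* AIC uses the package's own parameter count (fixed + variance
  components + residual); REML fits are never ranked against ML fits.
* Degenerate inputs return `None`/missing rather than raising wherever
  the quantity is optional downstream (no bracketing pair at 250 m, a
  phase not reaching 200 m, < 5 points for a breakpoint, an empty noon
  window); hard errors are reserved for contract violations (missing
  tag columns, non-positive intensity, non-uniform sampling in the lag
  correction).

## Known limitations

* The ZOC routine is a windowed-mode stand-in for the unpublished
  "customised" routine; it assumes the tag surfaces at least hourly in
  most 6-h windows.
* Light "profiles" feed the broken stick on the raw level scale (the
  scale the sensor reports); using calibrated intensities would weight
  deep structure differently.
* One light profile = one dive (not one phase) when counting the ≥ 3
  profiles per seal-day.
* The monthly band-means product defaults to the 55–65 °S band.
* `MixedLM` SEs are conditional on the selected structure;
  post-selection uncertainty is not propagated (as in the original
  procedure).
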