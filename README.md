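# sealight

A phytoplankton index from seal-borne time-depth-light records.

Archival tags on southern elephant seals record depth, ambient blue
light and temperature every 30 s for entire foraging trips.  In Case-1
waters, where phytoplankton dominates optical attenuation, the decay of
light with depth indexes phytoplankton density — wherever and whenever
the seal dives, including high latitudes and seasons where satellite
ocean colour is blinded by cloud and ice.  `sealight` turns raw tag
records into the integrated light-attenuation index

    LA250 = (LL_0 − LL_250) / 250 m        [levels per metre]

where `LL_0` is the mean near-surface light level at the end of a
dive's ascent and `LL_250` the level interpolated at 250 m.  The tag
log-compresses intensity at 20 levels per decade, so LA250 is
`(20/ln 10) · K̄` with `K̄` the mean diffuse attenuation coefficient of
the top 250 m, and is invariant to surface irradiance and tag
sensitivity.  Daily local-noon index values are gridded at 1° × 8 days ×
seal against satellite chlorophyll-a composites and related to them
through AIC-ranked log-log linear mixed-effects models (random intercept
and LA250 slope by seal), giving a light-based chlorophyll estimate
(`TDLR_chl`) along each seal's track.

The package covers the full chain — zero-offset depth correction, dive
segmentation, broken-stick mixed-layer and light-inflection depths,
T200-based frontal-zone classification, sensor calibration, the noon
index, gridding/filter rules, model selection — plus a synthetic-data
generator (`OceanTruth`, `generate_track`, `generate_dive_series`,
`generate_satellite_products`) that plants known structure so every
stage is testable end to end.  See `docs/methods.md` for the science
and the design decisions.

## Worked example

The `analysis/` scripts run a complete synthetic campaign — six
deployments staggered a week apart from 1 October, 100 days each —
through the whole pipeline, writing tables under `results/`:

```sh
cd analysis
python 01_generate_cohort.py    # tag records + tracks -> scratch/
python 02_dive_metrics.py       # segmentation, MLD / light inflections
python 03_noon_index.py         # daily noon LA250 + frontal zones
python 04_grid_and_match.py     # satellite emulation + 1-degree gridding
python 05_model_selection.py    # 16-model AIC ranking + REML fit
python 06_summaries.py          # predictions, error bands, coverage
```

Selected output (script 03, then 05):

```
600 seal-days with noon profiles; 543 analysable (>= 3 light profiles)
light profiles per seal-day: 3.8 +/- 0.9
...
final model (REML): LA250+lat+S
                     estimate      se       p
Intercept              1.5476  0.1225  0.0000
C(season)[T.summer]    0.1910  0.0497  0.0002
la                     2.1134  0.1080  0.0000
lat_c                 -0.0872  0.0075  0.0000

LA250 coefficient 2.113 +/- 0.108
planted phytoplankton exponent beta_true = 1.0; the cohort-mean
surface/column coupling slope (1.15) and clear-water dilution (1.87)
imply a coefficient near 2.15
```

Reading this: each seal-day yields ~4 usable noon light profiles; model
selection keeps LA250, season and latitude; and the fitted log-log
LA250 coefficient (2.11 ± 0.11) matches the structural expectation for
this ocean — the planted phytoplankton exponent is 1, amplified by the
seasonal-latitudinal surface/column coupling of the synthetic world
(×1.15 averaged over the cohort) and by the clear-water share of
attenuation (`k/(k − k_water) ≈ 1.9` at the median observed
attenuation).  Setting `k_water ≈ 0` (phytoplankton-dominated water)
and evaluating at the reference season and latitude makes the expected
coefficient exactly 1; the test suite's recovery experiment verifies
that the full pipeline then covers the planted unit slope within 2 SE
in ≥ 93 of 100 seeded replicates.

Script 06 adds the summary products: signed prediction-error
proportions by 1000-m bathymetry band, index-vs-satellite data coverage
by latitude and month (75 % of analysable seal-days matched a
cloud-free composite in this cohort), and monthly means of light-based
vs satellite chlorophyll in the 55–65 °S band.

A thin CLI wraps the same library for real tag files:

```sh
sealight segment tag.csv --out dives.csv
sealight profiles tag.csv --out features.csv
sealight index tag.csv positions.csv --out noon_index.csv
sealight model noon_index.csv --chl chl_*.nc --ice ice_*.nc \
    --bathy bathy.nc --outdir model_out
```

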