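# skystrip

Dual-platform strip-transect survey analysis: compares dugong-style counts
from human observers and drone imagery collected over the same transects.
The package implements the full analysis chain as reusable, file-oriented
stages, exercised end-to-end on synthetic surveys with known ground truth:

- **synthetic_data** — synthetic surveys: parallel transect layouts,
  clustered animal groups with zero-truncated heavy-tailed sizes, per-image
  telemetry, per-occasion Bernoulli detections for both platforms, and
  piecewise-constant environmental covariates (water visibility, sea state,
  sun glitter, cloud okta).
- **geometry** — pinhole projection of tilted camera frames onto the sea
  surface: footprint polygons, forward-/side-lap, minimum-bounding widths,
  dissolved coverage, segment cuts, capture-interval scheduling for a target
  forward-lap, observer effective areas and zone-centre sighting positions.
- **sightings** — duplicate resolution across overlapping frames, 200 m
  chain-rule grouping (single-linkage connected components), observer
  front/back call matching and multi-reviewer capture histories.
- **segments** — constant-visibility transect segments carrying
  per-platform areas, covariates and tallies; the count-model sample units.
- **perception** — Huggins closed-capture conditional likelihood on the
  logit scale; candidate structures (constant / by role / by side /
  saturated, plus covariate models) ranked by AICc; combined probability
  `1 - prod(1 - p_i)` with delta-method SE.
- **samplesize** — the minimum-detections precision simulation: a 7-value
  probability grid crossed with 8 detection levels (392 two-reviewer /
  2,744 three-reviewer scenarios), conditional history simulation, per-
  replicate Huggins fits, CV summaries and an asymptote rule.
- **count_models** — Tweedie quasi-likelihood count regression (log link,
  log-area offsets, optional flight / transect-in-flight random intercepts
  via penalised quasi-likelihood), variance-power profiling, zero-truncated
  Poisson group-size regression, Wald backwards selection, effect ratios.
- **pipeline** — one-command orchestration with a reproducible manifest and
  a consolidated report.

## CLI

```sh
# full pipeline: simulate -> footprints -> dedupe/group -> segments ->
# perception -> sample-size demo -> count models -> report
skystrip run --out out/ --seed 7

# individual stages
skystrip simulate --config cfg.yaml --seed 7 --out out/
skystrip perception --histories out/histories_observer.csv --models constant,by_role
skystrip samplesize --reviewers 2 --reps 1000 --seed 11 --p 0.7,0.7 \
    --levels 25,100,500 --out scenarios.csv
```

`skystrip run` writes, per stage: the canonical CSV tables (`images.csv`,
`detections.csv`, `calls.csv`, `track.csv`, `cloud.csv`, `truth.csv`),
`footprints.geojson` + `coverage.csv`, `groups.csv` + history tables,
`segments.csv`, `perception.json`, `scenarios.csv`, `models.json`, and
`report.json` / `report.md` plus a `manifest.json` with per-stage digests
(identical config + seed reproduces identical digests).

## Conventions

All computation happens in a local planar metric frame (easting/northing,
metres) with the sea surface as the plane z = 0. Camera rays are rotated
azimuth → pitch → roll → mount tilt; azimuth is degrees clockwise from
north, and positive tilt/roll swing the view to starboard.
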