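# catmove

Movement-ecology pipeline for GPS-collared free-roaming cats: trajectory
cleaning, home-base/time-away and daily-distance metrics, Brownian-bridge
kernel home ranges, and the accompanying regression stage — validated
end-to-end against a simulator with known ground truth.

## What it does

| Module | Role |
| --- | --- |
| `catmove.tracks_io` | GPX/CSV track reading, home anchoring, duplicate removal, per-cat 5/10 m/s speed filtering, local planar projection |
| `catmove.movement_metrics` | per-day time away from the 50 m home base, daily distance, first/last-day trimming, interruption flagging |
| `catmove.bbkde` | Brownian-bridge kernel utilization distributions, sigma1 estimation by leave-one-out likelihood, 50/95% isopleth areas, MCP comparison areas |
| `catmove.inference` | chi-squared association screen, beta regression (logit link) for time budgets, Box-Cox + AR1 linear mixed model for daily distance, log-scale OLS for home range, type-II tests, backward elimination, confounding checks, Tukey pairwise contrasts, rainfall prediction curves |
| `catmove.simulate` | two-state (home dwell / OU excursion) movement simulator with accelerometer-style device sampling, Gaussian location error, blunder injection and full ground truth |
| `catmove.pipeline` / `catmove.cli` | staged orchestration with TOML config, deterministic artifacts and report tables |

## CLI

```bash
catmove all --seed 42 --out run1           # simulate -> clean -> ... -> report
catmove simulate --config my.toml
catmove clean --out run1                   # individual stages
```

Stages: `simulate`, `clean`, `metrics`, `homerange`, `models`, `report`.
Config is a flat TOML file mirroring `catmove.pipeline.RunConfig`
(home radius, speed-filter band count, UD grid cell, alphas, Box-Cox
handling, timezone, ...). Exit codes: 0 ok, 2 config error, 3 data error,
4 model error. Reruns with an identical config and seed are byte-identical.

Artifacts written per run: cleaned tracks, `daily_metrics.csv`,
`cat_summary.csv`, `homerange.csv`, coefficient tables
(`table1_timeaway.csv`, `table2_distance.csv`, `table5_homerange.csv`),
rainfall predictions (`table3_rainfall.csv`), stratified descriptives
(`table4_descriptives.csv`), elimination traces, confounding reports and an
exclusion log with machine-readable reason codes.

## Notes

- Raw study data are not redistributable; every test input is generated
  programmatically by `catmove.simulate`, which reproduces the device's
  2-10 min moving / 60 min stationary cadence and ~13 m location error.
- The distance response uses the plain power transform `y**lambda`
  (metre-scale intercepts are only consistent with back-transformed
  predictions on that scale); the normalized Box-Cox variant is available
  via `power_mode="normalized"`. Home-range areas are modelled on log10 by
  default (`log_base` configurable).
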