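# matchload

Minute-by-minute energy-expenditure intensity analysis for soccer GPS
wearable data.

The package fuses two provider-level data streams — discrete
metabolic-power events (MPEs: short high-intensity phases with duration
and average power) and 5-minute aggregate GPS/energetic metrics — into a
25-feature table with one row per player-minute. Minutes are clustered
into low/middle/high intensity zones (min-max scaling, PCA, K-means with
WCSS-elbow model selection), and the resulting zone fractions are compared
game by game against conventional whole-game speed-band metrics via the
coefficient of variation. A Markov-chain module estimates per-player
intensity-transition matrices and condenses them into a bounded fitness
score for tracking across training cycles. A synthetic game simulator with
known hidden intensity regimes provides ground truth for every stage.

## Command line

Everything is reachable through one entry point:

```sh
# synthetic corpus with known regimes (mpe.csv, gm5.csv, game_totals.csv,
# game_meta.json, truth.csv)
matchload simulate --out data/ --seed 7 --n-games 20

# per-minute feature table (25 features + exclusion flag)
matchload build-features --mpe data/mpe.csv --gm5 data/gm5.csv \
    --meta data/game_meta.json --out minutes.csv

# intensity model + per-minute zone assignments
matchload cluster --features minutes.csv --out model.json \
    --assignments assignments.csv --k-grid 2:15 --seed 17

# per-game load summaries and the CV comparison report
matchload analyze --assignments assignments.csv \
    --totals data/game_totals.csv --meta data/game_meta.json \
    --report report.json

# per-player Markov fitness scores
matchload mfit --assignments assignments.csv --group-by game --out mfit.csv

# or all stages at once, with a reproducibility manifest
matchload pipeline --out run/ --seed 17
```

`pipeline` also accepts `--config run.yaml`; CLI flags override the YAML.
Config keys and defaults: `ceiling_quantile: 0.995`,
`distance_threshold_m: 200`, `k_min: 2`, `k_max: 15`,
`variance_target: 0.92` (or `n_components`), `smoothing_alpha: 0.5`.

## Data dialects

CSV, UTF-8, comma-separated, `.` decimal. Time is seconds since first-half
kickoff and runs continuously through halftime.

* `mpe.csv` — `game_id,player_id,start_s,end_s,duration_s,max_speed_kmh,avg_power_wkg[,energy_jkg]`;
  event energy is average power x duration and is derived when absent.
* `gm5.csv` — one row per player per fixed 5-minute window (distance,
  MPE count, anaerobic energy, average metabolic power, average MPE
  time/recovery time/recovery power, walk/running distance and energy,
  general energy).
* `game_totals.csv` — whole-game totals per player: total distance,
  walking distance, running distance below 20 km/h, distance above
  20 km/h.
* `game_meta.json` — kickoff, half boundaries, goals, lineup with
  positions and on/off times.

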