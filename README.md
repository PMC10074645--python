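# presstrack

Trajectory reconstruction for **multi-sensor bird geolocators** that record
atmospheric pressure and light.  Miniature loggers (~1 g) cannot carry GPS;
instead, the pressure a stationary bird records is a fingerprint of the
local weather, and matching it against a gridded hourly atmosphere (an
ERA5-style reanalysis at 0.25°) locates the bird to within a grid cell —
far more precisely than classical light-level geolocation, which is nearly
uninformative in latitude around the equinoxes.  `presstrack` implements
the full analysis chain for songbird-scale migration studies:

1. **Activity segmentation** — split the pressure series into stationary
   periods and migratory flights (rate-threshold proposal; curated labels
   override).
2. **Pressure geolocation** — per stationary period, a likelihood map over
   grid cells: `exp(−w·n·MSE/2σ²)` on the demeaned hourly pressure match,
   masked by altitude plausibility against each cell's terrain elevation
   range.
3. **Light geolocation** — twilight detection, "in-habitat" calibration of
   the solar zenith-angle distribution by KDE, per-period maps pooled
   log-linearly with weight 1/k.
4. **Trajectory HMM** — grid cells as states, combined maps as emissions,
   and a movement model on **airspeed**: the transition weight is
   `P(v)^(−1/3)`, the inverse cubic root of the mechanical flight power
   `P(v) = α/v + βv³` (Wheatear-sized morphology), with the wind vector
   subtracted from the ground vector and a 20 km/h airspeed floor.  Exact
   forward–backward marginals, Viterbi most-likely path, 100 posterior
   path simulations, and 0.99 credible regions.
5. **Flight metrics** — barometric altitude series per flight, positive
   altitudinal change, ground speed / wind support / airspeed / distance,
   summarized by five flyway regions (Europe, Mediterranean, Atlas,
   Sahara, Sahel) and season.
6. **Local movements** — diel roost-commuting detection (night vs day
   altitude, 50–300 m band) and multi-hour altitudinal excursions.
7. **Cohort statistics** — tag-effect return-rate tests on 2×2 tables
   (continuity-corrected proportion test, Fisher exact).
8. **Synthetic world** — a ground-truthed simulator (AR(1)×spatially
   correlated pressure field, smooth topography and wind, nocturnal
   flights, noisy logger readout) so that every stage is testable without
   downloading reanalysis data.

The HMM stage follows the model/results pattern: build a
`TrajectoryModel` from emission maps and pooled flight durations, call
`.fit()`, and work with the returned `TrajectoryResults`.

## Worked example

```python
from presstrack import WorldConfig, generate_world, default_truth, simulate_bird
from presstrack.pipeline import RunConfig, run_track
from presstrack.world import score_recovery

cfg = WorldConfig(seed=1)                       # 15×15 grid, 0.25°, 90 days
world = generate_world(cfg)                     # hourly gridded atmosphere
truth = default_truth(world, cfg)               # 8-site migration scenario
series, timeline = simulate_bird(world, truth, cfg=cfg)

res = run_track(series, timeline, world, RunConfig()).results
print(res.summary().to_string(index=False))
print(score_recovery(res, truth, world))
```

Output:

```
 period mlp_cell  marginal_max  mlp_marginal  cr99_cells   lat   lon
      0   (1, 7)      0.999958      0.999958           1 45.75  9.75
      1   (5, 6)      0.221022      0.221022           9 44.75  9.50
      2   (7, 8)      0.996881      0.996881           1 44.25 10.00
      3   (9, 7)      0.090919      0.090919          48 43.75  9.75
      4  (10, 7)      0.114975      0.112041          53 43.50  9.75
      5  (11, 7)      0.145719      0.145719          31 43.25  9.75
      6  (12, 7)      0.153060      0.153060          39 43.00  9.75
      7  (13, 7)      1.000000      1.000000           1 42.75  9.75
{'median_error_km': 0.0, 'pct_within_1_cell': 100.0, 'pct_truth_in_cr': 100.0, 'n_periods': 8}
```

Each row is one stationary period: the most-likely grid cell, the posterior
mass it holds, and the number of cells in the 0.99 credible region.  Long
stationary periods (rows 0, 2, 7) pin the bird to a single cell; one-day
desert stops (rows 3–6) are genuinely more uncertain, yet the most-likely
path still recovers the true cell for every period of this simulation and
every truth cell lies inside its credible region.

The same pipeline runs from files (logger CSV, label CSV, atmosphere
NetCDF) via the CLI:

```bash
presstrack simulate --seed 1 --out sim/
presstrack fit --logger sim/logger.csv --labels sim/labels.csv \
               --atmosphere sim/atmosphere.nc --out run/
presstrack metrics --out-dir run/
presstrack tag-effect --table 66 74 20 34
```

`flights.csv` holds one row per flight (duration, max/mean altitude,
positive altitudinal change, climb rate, ground speed, wind support,
airspeed, distance, region, season); `summary.csv` the per-region × season
means ± sd.

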