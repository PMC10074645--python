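# Methods

This note documents the models, the numerical choices and the synthetic
test bed behind `presstrack`, in the spirit of the methods appendices of
statistical packages: what is computed, under which assumptions, and what
the defaults mean.

## Coordinate and unit conventions

All timestamps are UTC.  The atmosphere grid is regular; cell centers
define the grid; cell (i, j) covers the half-open box
[center − res/2, center + res/2) in both axes, latitude rows ordered
north → south, matching reanalysis conventions and making point-in-cell
lookup unambiguous.  Pressure is stored in hPa, altitude in m a.s.l., wind
in m/s; speeds are converted to km/h only at reporting boundaries.  The
logger sampling interval defaults to 1800 s and is configurable (device
intervals vary between tag programmes).

## Barometric transform

Altitude and pressure are linked by the hypsometric equation under a
linear lapse (ISA constants: L = 0.0065 K/m, R = 8.3144598 J/(mol K),
g = 9.80665 m/s², M = 0.0289644 kg/mol, T_ref = 288.15 K):

    z = z_ref + (T_ref/L) · (1 − (p/p_ref)^(R·L/(g·M)))

The inverse is exact; the altitude→pressure→altitude round trip is
limited by floating point only (measured < 1e-11 m over 0–6000 m and
reference pressures 950–1040 hPa).  Reference surface pressures are
reduced to sea level with the same transform before use, so cell terrain
elevation does not bias flight altitudes.

## Pressure geolocation

For a stationary period, logger pressure is averaged within each
atmosphere hour and compared to each cell's surface-pressure series after
demeaning both; the constant offset removed by demeaning is exactly the
altitude information, which is scored separately.  Per cell:

    L(cell) = exp(−w · n · MSE / (2σ²)) · 1[implied altitude plausible]

* **σ = 1 hPa** — measurement/representativeness scale of the match.
* **w = 0.1** — log-linear down-weighting.  Hourly weather is strongly
  autocorrelated; n correlated samples carry far fewer than n effective
  observations, and w < 1 keeps maps from becoming overconfident.  (The
  effective sample size of an AR(1) series with coefficient 0.95 is
  roughly n/39, so w = 0.1 is deliberately conservative rather than
  optimal.)
* **Altitude plausibility** is a hard mask: the altitude implied by the
  mean logger pressure against the cell's mean surface pressure must fall
  within the cell's terrain range [elev_min − 150 m, elev_max + 150 m].
  The margin absorbs weather-induced offset error and birds perched above
  the terrain model.  A soft altitude penalty would be a defensible
  alternative; the mask was chosen because the terrain bound is a
  feasibility constraint, not a noisy measurement.
* Periods with fewer than 3 overlapping hours contribute a mask-only map.

Empirically (seeded tests), the true cell's posterior rank improves
monotonically as the period grows from 6 h to 5 days.

## Light geolocation

Twilights are threshold crossings of the light series with linear
interpolation between samples.  At a known calibration site the solar
zenith angle (NOAA/Meeus geometry, geometric zenith, no refraction;
agreement with an independent low-precision almanac formula is well under
0.5°) is evaluated at each calibration twilight; a Gaussian KDE (Silverman
bandwidth unless configured) summarizes the distribution.  For an unknown
period each twilight scores every cell by the calibrated density at the
zenith the sun would have had there; k twilight maps are pooled as the
geometric mean, exp((1/k)·Σ log density), so duplicated twilights never
sharpen the map.  The equal-weight pooling is the natural default when no
per-twilight quality measure is available.  Light maps mainly constrain
longitude; latitude information collapses near the equinoxes, which is
why pressure is the primary source.

Pressure and light maps are combined by cell-wise product (independence
of the two error processes) and renormalized; disabling one source
degenerates exactly to the other.

## Trajectory HMM

States are grid cells, one step per stationary period, emissions the
combined maps.  Transitions use an airspeed movement model: ground vector
from great-circle distance (R = 6371 km) and initial bearing over the
pooled duration of the flights linking two consecutive periods
(multi-flight nights sum their durations); wind (time-mean over the
flight window, space-mean of the origin/destination candidate cells) is
subtracted to give airspeed; the weight is

    P(v)^(−γ),   P(v) = α/v + β v³,   γ = 1/3

with α = 2(mg)²/(ρπb²), β = ½ρS_bC_Db for a 25 g, 0.29 m wingspan bird
(ρ = 1.0 kg/m³, S_bC_Db = 0.00181 m²).  P is strictly convex with minimum
at v_mp = (α/3β)^(1/4).  γ is exposed as a configuration key because the
inverse-cubic-root reading of the power→probability mapping is one of
several defensible choices; airspeeds are floored at 20 km/h so that
zero-displacement transitions (local or exploratory flights) keep a
finite, flat cost.  Transitions implying ground speeds above 150 km/h are
pruned for tractability and rows renormalized over reachable cells.

Inference is exact: scaled forward–backward for per-period marginals,
Viterbi (ties broken toward the lowest flattened cell index — numpy's
first-argmax) for the most-likely path, and backward sampling from the
filtered distributions for posterior path simulations (default 100,
seeded).  Credible regions are the smallest sets of highest-probability
cells reaching the target mass (default q = 0.99).  On 100 random toy
instances (≤ 5 periods × ≤ 12 cells) marginals agree with exhaustive path
enumeration to < 1e-10 and the Viterbi path is identical.

## Flight metrics

Per flight: altitude series from the barometric transform against the
hourly sea-level-reduced reference at the most-likely location; maximum
and mean altitude; positive altitudinal change (sum of positive altitude
increments) and its rate per flight hour; great-circle distance, ground
speed, wind support (wind projected on the track bearing) and airspeed.
Flights are assigned a single region by the great-circle midpoint of the
transition.  The default region partition is a configurable latitude-band
approximation (Europe ≥ 43°N, Mediterranean 37–43°, Atlas 30–37°, Sahara
18–30°, Sahel 10–18°); real analyses should supply proper polygons.
Seasons split at the calendar half-year (departures Jul–Dec = autumn).
Summaries pool all flights within a category (no per-bird averaging);
groups of size one report sd = 0 with an explicit flag.

## Local movements

Altitude within a stationary period is reconstructed as for flights.
Diel commuting: samples are split at civil twilight (solar zenith 96°)
into day/night runs; each daylight run is paired with the following
night; a pattern is detected when the night-minus-day median delta stays
within 50–300 m for ≥ 3 consecutive days.  The band matches the roost
offsets reported for alpine passerines; the thresholds are package
defaults, not estimated quantities.  With altitude noise of 30 m the
false-positive rate is ≤ 5% over 100 seeds.  Excursions are maximal runs
≥ 6 h at ≥ 300 m from the period's median altitude; two separated
departures remain two events.

## Cohort statistics

Return rates of tagged vs control birds: the 2-sample proportion test
with continuity correction (equivalently Yates-corrected χ² on the 2×2
table, 1 df) and the two-sided Fisher exact test by the probability
method (sum of hypergeometric probabilities of tables no more probable
than observed).  Both are verified in the tests against the closed-form
χ² and a full enumeration oracle.

## Synthetic world

The simulator generates the statistical structure the pipeline assumes,
not meteorological realism:

* **Pressure**: sea level p₀ = 1013.25 hPa + 0.5 hPa/cell eastward
  gradient + a weather process that is AR(1) in time (coefficient 0.95,
  innovation sd 1 hPa — lag-1 autocorrelation verified at 0.95 ± 0.02)
  with squared-exponential spatial correlation (length 3 cells, exact via
  Cholesky of the cell covariance).  Stationary sd ≈ 3.2 hPa, comparable
  to synoptic variability.
* **Terrain**: a smoothed random topography spanning 0–3000 m, each cell
  carrying a ± 200 m elevation half-width.
* **Wind**: a time-constant smooth field around a configurable mean
  (default gentle north-westerly support).
* **Bird**: the default scenario mirrors a trans-Saharan migration
  compressed to desk scale — breeding site, coastal stop, one long
  stopover, four one-day desert stops, and a non-breeding site holding
  the remainder of the 90-day span, linked by nocturnal great-circle
  flights with trapezoidal climb/cruise/descent altitude profiles.  On a
  15×15 × 0.25° grid, hop distances cap near 400 km, so flight durations
  follow from the site spacing at ground speeds of 30–60 km/h (≈ 1–8 h)
  rather than the double-digit hours of real barrier crossings; the
  simulator keeps every duration consistent with a 20–80 km/h ground
  speed.
* **Logger**: pressure at the bird's altitude via the barometric
  transform plus Gaussian sensor noise (default 0.5 hPa); light is a
  logistic function of the solar zenith at the true position (midpoint at
  zenith 96°) plus noise.

What passing tests show — and do not show: the recovery results (median
100% of periods within one cell over 20 seeds; 100% credible-region
coverage) demonstrate the correctness of the inference machinery under
the generator's assumptions.  Real data add un-modelled structure —
diurnal pressure tides, logger drift, birds moving within a "stationary"
period, terrain model error, wind shear across pressure levels — so field
accuracy will be lower and must be judged against ringing recoveries or
known sites, not against these simulations.

## Problem sizes and determinism

Default test and reproduction sizes: 20 synthetic seeds at the full
15×15 × 90-day configuration, 100 random HMM instances capped at 250 000
enumerated paths, 100 noise seeds for the diel false-positive rate, and
10 000 posterior samples for the sampling-frequency check.  Every random
draw flows from an explicit integer seed (`numpy.random.default_rng`);
rerunning any pipeline with the same configuration and seed reproduces
its CSV outputs byte for byte.

## Known limitations

* Surface-level pressure matching only; no pressure-level selection for
  flight winds.
* The latitude-band region partition is a stand-in for real region
  polygons.
* Light calibration windows must be supplied by the analyst; no automatic
  selection of equipment/retrieval periods.
* The hard altitude mask can reject a true cell if the terrain model is
  badly wrong; the 150 m margin is the only guard.
* No attribution of excursions to weather covariates.
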