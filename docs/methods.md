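# Methods

`adaptsample` implements a temporally adaptive scheduling algorithm for
autonomous acoustic recording units (ARUs) that can receive next-day
instructions over a network, together with the simulation environment
needed to evaluate it against stationary baselines. This note documents
the model, the numerical choices, and what the synthetic world does and
does not establish.

## The capture-probability framework

For each focal species *k* at each monitoring site *r*, the quantity of
interest is **p\*** (*p(capture)*): the probability that the species has
been recorded at least once so far, conditional on presence. Monitoring
at a site continues for a species until p\* reaches a user-set threshold
**p\*_max** (default 0.95), after which the species is released from
priority there.

The chain from hourly biology to p\* is:

1. **Hourly vocalization probability.** Each species carries a logistic
   model over site-hour covariates:
   `M = β₀ + Σⱼ βⱼ·fⱼ(xⱼ)`, `p_v = exp(M)/(1+exp(M))`,
   where the transforms `fⱼ` are identity, square, cube, or sine/cosine
   with an explicit period (366 for day of year, 183 for days since the
   most recent equinox, 24 or 12 for hour of day, 1 for lunar-phase
   fraction). Periodic shorthand in the shipped coefficient tables always
   means `sin/cos(2π·x/P)`. Polynomial terms act on raw covariate scales
   — the shipped coefficient magnitudes (e.g. 10⁻⁶ on temperature³) only
   make sense unstandardized. Nine desert focal-species models ship as a
   versioned CSV fixture; user models use the same format.

2. **Minute bridge.** p_v is the probability of at least one vocalization
   in an hour. Treating the hour as a homogeneous availability process,
   one 1-minute sample detects with
   `p_min = 1 − (1 − p_v)^(1/60)`,
   so m samples in an hour miss with probability `(1−p_v)^(m/60)` and 60
   samples recover p_v exactly. This bridge is an explicit modeling
   choice: nothing in the capture framework dictates how sub-hourly
   effort scales, and a config switch (`minute_scaling=False`) provides
   the alternative hour-level reading in which any sampled hour
   contributes p_v once. The minute-scaled default is used everywhere
   because the factorial design (up to 30 samples in a single hour) is
   meaningless if within-hour effort does not matter.

3. **Daily and cumulative accounting.** A day's detection probability
   under a schedule is the complement product over its samples, and
   `p*ₙₑw = 1 − (1 − p*)(1 − p*_d)`. Detections are assumed independent
   across minutes, hours and days; this is implicit in the product-form
   capture accounting and is the standard assumption of the framework.

## The adaptive schedule

Each day, for each site:

- **Score** each of the 24 clock hours as the dot product of the current
  species priority weights with the species' p_v for that hour.
- **Allocate** the daily effort S (1-min samples) greedily: hours ranked
  by score, at most 30 samples per hour (a field constraint: short files
  transmit reliably over cellular links), overflow cascading to the next
  hour. Within an hour, m samples start at minutes `round(j·60/m)`,
  which guarantees the required ≥ 1-min buffer for m ≤ 30. Equal scores
  are broken toward the earlier clock hour — the tie rule is arbitrary
  but fixed, so runs are reproducible.
- **Update weights** after accounting:
  `raw_k = w0_k · max(0, 1 − p*_k / p*_max,k)`, renormalized site-wise to
  sum to one; a species past threshold gets exactly zero, and a site
  where every species is satisfied is released entirely. The linear
  shrinkage form is the simplest satisfying the required shrink/grow
  behavior and the zero-at-threshold rule; no claim is made that it
  matches the original field implementation's unpublished functional
  form, so day-level agreement with that implementation's outputs is not
  expected.

Sites are scheduled independently; cross-site pooling of effort is a
documented non-goal. Scheduling for day d+1 uses forecast covariates; by
default the simulator returns the realized covariates as the forecast
(forecast = truth), with an optional additive forecast-noise hook.

A relaxed mode accepts thresholds above 1 by reinterpreting the stop
metric as expected capture-days `Σ_d p*_d` (e.g. threshold 2.0 ≈
"captured on about two distinct days"); it is off by default and shares
the same shrinkage form.

## The synthetic weather world

The real study consumed a commercial hourly weather feed that no longer
exists, so the generator emulates the study area's published monthly
summaries (mean/sd/min/max temperature and wind, mean/max 24-h rain):

- **Temperature** = monthly mean + diurnal sinusoid (peak 15:00, trough
  03:00 local standard time) + Gaussian noise, clipped to the monthly
  envelope. The tabulated sd describes realized hourly temperatures, so
  it is split: 60 % of the variance to the sinusoid, 40 % to noise. Means
  and sds then match the tables by construction and clipping is a
  > 3.5σ event.
- **Wind** is Gamma with the monthly mean and sd (support ≥ 0 keeps the
  mean exact without rejection), clipped to the monthly maximum. Hours
  are i.i.d.; there is **no diurnal wind cycle**, a known simplification
  (deserts are calmer at dawn than mid-afternoon, which would favor
  dawn-singing species).
- **Rain** is storm-clustered: a site-day is a storm day with probability
  `p_storm = rain24_mean / (6·μ)` where wet-hour depths are exponential
  with mean `μ = rain24_max / 8`; a storm is a contiguous 6-hour spell.
  The expected hourly depth matches the monthly mean exactly, and one
  storm accumulates ~¾ of the monthly maximum, so realized 24-h maxima
  are of the tabulated order. Unclustered hourly rain would match the
  mean while producing several-fold too many distinct wet 24-h windows
  and maxima ~3× too small.
- **Astronomy.** Sunrise/sunset from standard solar geometry (Spencer
  Fourier series, zenith 90.833°), accurate to a few minutes at
  mid-latitudes; lunar phase as the fractional lunation from a fixed
  reference new moon (2000-01-06 18:14 UTC, synodic month 29.530588 d),
  accurate to ~±0.02 lunation — ample since models use only cos(phase).
  All clock times are local *standard* time (UTC offset = nearest
  15° meridian); daylight-saving shifts are ignored as a clock artifact
  with no biological content.

Derived covariates: trailing 24-record rain accumulation (a spin-up day
is simulated so the first output row has a full window); absolute minutes
to the *nearest* sunrise and sunset (continuous across midnight); days
since the most recent equinox wrapped into 1–183 (the Mar→Sep half-year
is 186 days; the wrap is harmless in the period-183 harmonics that
consume it).

Sites are independent — no spatial weather correlation, no habitat
covariates (the models are deliberately aspatial). A green test on this
world establishes that the algorithm behaves as specified under a
realistic desert covariate regime; it does not certify performance under
any particular realized year of weather, and exact day-level results from
the original study are not reproducible targets.

## The factorial experiment

2 treatments × 6 efforts (S ∈ {2,5,10,20,30,40}) × 2 durations (full
2016 leap year, 9 species; March only, 8 species — the monsoon-breeding
spadefoot is inactive and omitted). Both treatments in a cell consume the
identical p_v grid (paired design; weather is seeded per duration via a
spawned child seed). The March run starts from fresh p* = 0 — it is an
independent treatment, not a window into the full-year run.

Metrics per species and cell:

- **AUC**: mean over days of the site-averaged cumulative p* (left
  Riemann, normalized by duration so a constant-1 series scores 1 —
  bounded and comparable across durations; whether the original analysis
  normalized is unstated, so this is a package choice).
- **Mean achievement date**: mean day-of-year of first threshold
  crossing over the sites that cross at all; undefined when none do.

The daily loop stops early once every species-site pair is past
threshold; the p\* series is carried forward so AUC remains well-defined.

## Numerical notes

- Complement products are computed in log space (`log1p`), with the
  p_v = 1 branch handled exactly; the cumulative recursion agrees with
  the direct product `1 − Π(1 − p*_d)` to 10⁻¹².
- The logistic link is evaluated with the two-branch stable form.
- All randomness flows from a single seed through
  `numpy.random.SeedSequence` spawning (weather per duration, site
  jitter), so enabling one stochastic component never perturbs another.
- Hour ranking uses a stable argsort on negated scores: deterministic,
  earliest-hour tie-break.

## Known limitations

- Wind lacks diurnal structure and weather lacks spatial correlation;
  both shift species' *absolute* availability levels. In particular, the
  rain-triggered spadefoot's annual mean availability under the tabulated
  storm regime lands marginally above the windiest-penalized songbird's,
  so the published three-lowest-species ranking reproduces only 2-of-3
  under this generator (the analysis lives with the test that measures
  it).
- Final p\* is *not* guaranteed monotone in S for the multi-day adaptive
  loop: greedy allocations are nested in S only at fixed scores, and
  weight trajectories diverge between effort levels. A rare species
  available on few days can end marginally lower at higher effort.
- The weight-update functional form, the minute bridge, and the AUC
  quadrature are package choices where the original description is
  silent; all are switchable or documented above.
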