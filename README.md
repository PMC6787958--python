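# adaptsample

Temporally adaptive acoustic sampling schedules for multi-species
wildlife monitoring.

## The problem

Autonomous recording units (ARUs) with constrained sampling budgets —
e.g. a handful of 1-minute recordings per day squeezed through a cellular
data plan — must be told *when* to record. A species that is present but
silent during every scheduled sample is logged as absent (a false
negative), and the risk compounds when one program tracks many species
whose calling windows shift with season, time of day, moonlight and
weather: desert songbirds own calm spring dawns, nightjars and coyotes
the night, and a spadefoot toad may vocalize only in the hours after a
monsoon storm.

`adaptsample` schedules recordings adaptively. For species *k* at site
*r* it tracks the cumulative probability of acoustic capture

    p* = 1 − Π_d (1 − p*_d),

the probability of having recorded the species at least once through day
*d* given presence, and re-plans every site's next day to push every
species' p\* toward a target `p*_max` (default 0.95) as fast as possible:

1. each species' hourly vocalization probability `p_v = logistic(M)` is
   predicted from a coefficient-table model over weather and
   astronomical covariates (day of year, hour harmonics, minutes to
   sunrise/sunset, temperature, wind, lunar phase, 24-h rain);
2. each site-hour is scored by the dot product of species priority
   weights with species p_v;
3. the daily effort S (1-min samples) fills the top-scoring hours, ≤ 30
   samples/hour, evenly spaced;
4. after each day p\* is updated and weights shrink as
   `w ∝ w0·(1 − p*/p*_max)⁺`, renormalized per site — satisfied species
   drop out and the schedule chases what is still missing.

The package ships the nine desert focal-species models, the monthly
weather summaries of a Sonoran-desert study area, a seeded synthetic
weather generator that emulates them, stationary baseline schedules for
S ∈ {2, 5, 10, 20, 30, 40}, and a paired fixed-vs-optimized factorial
experiment (2 treatments × 6 efforts × 2 durations) with AUC and
achievement-date metrics. Schedules export as CSV and as one iCalendar
file per site, matching field deployments where each ARU polls a
calendar.

## Worked example

Run the March factorial on five synthetic sites at the lowest and
highest sampling efforts:

```python
from adaptsample import default_models, default_sites
from adaptsample.experiment import default_durations, paired_comparison, run_factorial

sites = default_sites(5, seed=1)
models = default_models()
march = {"march_only": default_durations(models)["march_only"]}
results = run_factorial(sites, march, efforts=(2, 10, 40), seed=0)
print(paired_comparison(results).round(3).to_string(index=False))
```

which prints (S = 2 and S = 40 rows shown):

```
  duration  effort species_code  AUC_fixed  AUC_optimized  mean_achievement_doy_fixed  mean_achievement_doy_optimized  days_earlier
march_only       2         BTGN      0.062          0.259                         NaN                             NaN           NaN
march_only       2         ECDO      0.069          0.360                         NaN                             NaN           NaN
march_only       2         GAQU      0.089          0.415                         NaN                             NaN           NaN
march_only       2         PHAI      0.117          0.510                         NaN                             NaN           NaN
...
march_only      40         ECDO      0.779          0.947                        82.4                            67.2          15.2
march_only      40         GAQU      0.828          0.961                        77.6                            65.2          12.4
march_only      40         PHAI      0.893          0.977                        72.0                            64.0           8.0
march_only      40         VERD      0.809          0.956                        79.6                            65.8          13.8
```

Reading it: at two samples per day the adaptive schedule multiplies the
area under the capture curve (AUC, 1 = captured everywhere on day one)
several-fold over the fixed baseline; at forty samples per day both
approach saturation, but the adaptive schedule still crosses the 0.95
capture threshold 8–15 days earlier (`days_earlier`; `NaN` means no site
crossed under that treatment, e.g. the fixed schedule at S = 40 never
captures Black-tailed Gnatcatcher with 95 % confidence inside March,
while the optimized one does by day-of-year ≈ 70).

The same pipeline is scriptable from the shell:

```sh
adaptsample simulate-weather --n-sites 5 --start 2016-03-01 --end 2016-03-31 --seed 7 --out cov.csv
adaptsample predict-pv --covariates cov.csv --out pv.csv
adaptsample schedule --pv-csv pv.csv --date 2016-03-15 --effort 10 --out sched.csv --ics-dir calendars/
adaptsample run-experiment --config config.yaml --out comparison.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the core computation from scratch — it
generates synthetic sites and weather from the given seed, predicts the
nine species' hourly vocalization probabilities, executes the paired
fixed-vs-optimized factorial over both study durations at all six effort
levels, and reports the resulting JSON to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/adaptsample/solar.py`, `weather.py`, `covariates.py` — astronomy,
  seeded weather generator, site-hour covariate tables
- `src/adaptsample/models.py` — declarative logistic vocalization models
  and vectorized p_v grids
- `src/adaptsample/scheduling.py` — optimized allocator and fixed
  baseline schedules
- `src/adaptsample/capture.py` — p\* accounting and priority-weight
  updates
- `src/adaptsample/experiment.py` — the daily adaptive loop and the
  factorial comparison
- `src/adaptsample/config.py`, `ics.py`, `cli.py` — YAML configs,
  iCalendar export, command-line interface
- `docs/methods.md` — model assumptions, generator calibration, known
  limitations
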