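# phcworkload

Stochastic estimation of primary-healthcare clinical workload for a facility
catchment population, under region-specific demographic and epidemiological
trends.

## The problem

Primary-care systems are usually staffed against fixed population ratios
(e.g. two community health workers per 5,000 people). But the clinical time a
catchment actually demands depends on its age/sex structure, fertility and
mortality trends, local disease burden, and within-year seasonality — all of
which differ between regions and drift over a planning horizon. This package
is for health-workforce analysts who want a bottom-up, uncertainty-aware
workload projection instead of a ratio: it projects a catchment population
forward year by year, prices out a catalog of clinical tasks in minutes, and
propagates parameter uncertainty and trend stochasticity through Monte Carlo
simulation.

## The model

For every service task *s* in a catalog, the annual clinical time is

```
minutes_s = N_s × r_s × c_s × m_s
```

where `N_s` is the relevant population (a cohort selected by sex and age, or
the year's expected births for pregnancy-linked services), `r_s` the annual
incidence/prevalence proportion, `c_s` the number of contacts, and `m_s` the
minutes per contact. Total workload is the sum over the catalog.

Around this identity sit four layers:

* **Demography** — a cohort-component projection at single-year age
  resolution: age-banded fertility and mortality with multiplicative
  year-over-year change ratios (1.0 = no change), births entering at age 0.
* **Stochastics** — each Monte Carlo trial draws initial rates from a
  truncated normal (parameter uncertainty) and redraws every year's change
  ratios from a lognormal (trend stochasticity); zero spreads collapse the
  whole pipeline to a deterministic closed form.
* **Seasonality** — each task's minutes are spread over the 12 calendar
  months along a condition-specific curve (weights summing to 1), with
  per-contact month offsets (antenatal visits sit at negative offsets
  relative to the birth curve); non-seasonal tasks are spread evenly.
* **Scenarios** — a *growing* mode follows the projected population, a
  *fixed* mode rescales every year's pyramid to exactly 5,000 people while
  keeping its evolving shape; comparing the two isolates per-capita change
  from total growth. Cross-trial summaries report the median with 25–75 and
  5–95 percentile bands, peak-month-to-average ratios with a 90% interval,
  per-age/sex attribution, and fertility-trend sensitivity contrasts.

Real regional parameter sets are not distributed; the `synth` module
generates complete, validator-clean synthetic regions from three archetypes
(urban low-fertility-rising, rural high-fertility-declining, pastoral
high-fertility) with realistic structure.

## Worked example

```python
import phcworkload as pw

region = pw.generate_region("rural_high_fertility_declining", seed=2020)
cfg = pw.ScenarioConfig(region=region,
                        sampling=pw.SamplingConfig(master_seed=2020, n_trials=100))
summary = pw.summarize(pw.run_scenario(cfg))
med = summary.set_index("year")["p50"]
print(round(med.loc[2021], 1), "->", round(med.loc[2035], 1), "h/yr,",
      f"{pw.percent_change(med.loc[2021], med.loc[2035]):+.1f}%")
```

prints

```
6600.0 -> 8711.3 h/yr, +32.0%
```

i.e. for this synthetic rural region the median total clinical demand grows
from 6,600 to 8,711 hours per year over the fifteen-year horizon (+32%),
driven by population growth. Re-running the same region in `fixed_5000` mode
gives 6,488 → 6,281 h/yr (−3.2%): per-capita demand *declines* (infectious
tasks trend down at 2%/yr and the pyramid ages), so the total increase is a
pure population-growth effect.

The numbered scripts under `analysis/` walk the full study: `01` generates
one workbook per archetype under `results/params/`, `02` runs both
population modes (the numbers above), `03` computes peak-month seasonality
ratios (e.g. the pastoral archetype's peak month is ~60% above its average
month — planning on the average month would understaff it), `04` attributes
workload by age group and sex, `05` contrasts fertility-trend assumptions
(for the rural archetype, mirroring the declining trend into a rising one
lifts the 2035 median by ~10%).

A CLI mirrors the library: `phcworkload synth | simulate | summarize |
sensitivity` (see `--help`).

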