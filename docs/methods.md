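# Methods

## Task-time accounting

The unit of analysis is one clinical task: a service (e.g. treatment for
moderate acute malnutrition) applied to a *relevant population* at an annual
*rate*, requiring a fixed number of *contacts* of a fixed *duration*. Annual
minutes are the product of the four factors. Incidence and prevalence rates
are handled identically — both are read as the annual proportion of the
relevant population needing the service; the `rate_kind` field is metadata
only. Only direct clinical care is modelled: administrative work, training,
outreach and travel are out of scope, as are queueing and unmet-demand
effects.

Relevant populations come in two kinds. *General* specs select a standing
cohort by sex and inclusive age bounds in whole years (a service for
children aged 0–59 months spans ages 0–4, matching the pyramid's
single-year resolution). *Birth-linked* specs (antenatal care, delivery,
postnatal and newborn services) use the year's expected births as the
population; their age bounds are ignored.

## Demographic projection

Population state is a single-year age × sex pyramid over ages 0–100.
Five-year-banded inputs are interpolated by uniform split (each age in a
band receives 1/width of the band total), which conserves band totals
exactly; nothing finer is claimed than the banded sources support.

The yearly step applies, in a fixed documented order: (1) births computed
from start-of-year female counts via age-banded fertility, (2) mortality per
band, (3) aging by one year with age 100 absorbing for one year and then
exiting (no 101+ bin), (4) births entering age 0 split by a configurable sex
ratio (default 0.5/0.5). The order within a year is a convention, not an
empirical claim; with annual rates well below 1 the alternatives differ at
second order. Migration is not modelled.

Trends are multiplicative: a rate's year-over-year change ratio compounds
annually (0.98 = 2%/yr decline). In stochastic runs each year's realized
ratio is a fresh draw around the estimated trend, so trend uncertainty
accumulates over the horizon like a geometric random walk.

## Sampling model

Two uncertainty channels per parameter:

* initial level — drawn once per trial from a normal truncated at zero with
  mean equal to the point estimate and sd equal to the stated spread
  (proportions additionally capped at 1). Truncation uses the inverse-CDF
  method so each draw consumes exactly one uniform, keeping streams aligned.
* change ratio — redrawn each simulated year from a lognormal with median
  equal to the estimated ratio and log-sd equal to the spread, guaranteeing
  positivity; the geometric mean of draws recovers the estimated trend. A
  config switch (`redraw_change_each_year=False`) draws once per trial
  instead.

Both families are configurable; both return the point estimate exactly at
spread 0, which is the backbone of the test suite: a zero-spread run is a
closed-form spreadsheet calculation. Minutes-per-contact is samplable with
the same machinery (default spread 0). Trial streams are spawned from one
master seed via `numpy.random.SeedSequence`, making runs bit-reproducible
and trials statistically independent; the first *k* trials of an *n*-trial
run equal a *k*-trial run with the same seed. Draws are not correlated
across tasks or bands.

## Seasonality

A seasonality curve is 12 non-negative monthly weights summing to 1
(validated at 1e-9). Month *m* of a contact with offset *o* receives the
weight at position (*m* − *o*) mod 12; offsets wrap within the calendar year
rather than spilling into adjacent years — a steady-state approximation that
guarantees exact annual conservation, at the cost of mis-timing the year
boundary for strongly shifted contacts. Each contact carries an equal share
of the task's minutes with its own offset, so a four-contact antenatal
schedule at offsets (−6, −4, −2, −1) leads the birth curve. Tasks without a
curve are spread evenly, reflecting that only births, malnutrition, malaria,
diarrhea and TB have documented strong seasonality in this setting.

## Scenarios and statistics

`growing` mode follows the projection; `fixed_5000` rescales each year's
pyramid to total exactly 5,000 (the nominal catchment of one primary-care
facility) while preserving the evolving age/sex shape — the contrast
isolates structural change from growth. Per-capita workload divides a year's
minutes by the same year's post-step population.

Summaries are order statistics across trials per year: median, 25–75 and
5–95 bands (mean also emitted, since a skewed trial distribution makes the
two diverge and both are of interest). The peak-month ratio is the maximum
month divided by the mean month within a year (≥ 1 by construction),
summarised as a median with a 90% simulation interval. Reporting
conversions: hours = minutes/60; weekly hours assume 48 workweeks/year
(configurable); presentation rounding is to whole hours and whole percent
points.

Fertility sensitivity re-runs the scenario under alternative per-band
fertility change-ratio tables with a shared master seed (common random
numbers), so differences between variants are attributable to the
assumption alone; identical variants give exactly 0% difference. The flat
benchmark defaults to a 0.5%/yr decline (ratio 0.995) in every band — the
benchmark's level is a parameter because reasonable descriptions of "mild
decline" range over an order of magnitude.

In the age/sex attribution, each task's minutes are distributed over its
relevant population proportionally to cohort counts and aggregated to nine
reporting groups (infants, 1–4, then decadal bands to 65–100). Birth-linked
services are attributed to women aged 15–49 in proportion to female counts:
the design choice is that antenatal, delivery and postnatal contacts are
care delivered *to the mother*; attributing them to infants instead would
shift roughly the pregnancy category's share from women to the under-five
groups. Attribution conserves the grand total exactly.

## Synthetic regions

Real regional parameter workbooks are not distributed with the package, so
the generator produces structural stand-ins. Its defaults encode the study
conditions: a 5,000-person baseline pyramid in 2020, a 2020–2035 horizon,
100 trials for headline outputs (50 for the age attribution, which is the
expensive output), and a ~72-task catalog spanning 12 service categories —
family planning, nutrition, pregnancy, sick child, NCDs, malaria, NTDs,
sexual health, first aid, TB, HIV, mental health. Newborn immunization-type
tasks are carried under the pregnancy category as birth-linked services.

Archetype anchors are the few public reference points: urban fertility at
ages 20–24 near 0.1 births/woman/yr and rising vs rural near 0.235 and
declining (pastoral near 0.27, roughly flat); under-five population shares
of 8% (urban), 11% (pastoral), 15% (rural); infectious-disease incidence
declining at 2%/yr; malnutrition-style treatment rates up to ~45% of
under-fives. Jitter ranges are chosen so an archetype's identity (the level
window and the trend's direction) survives any seed. Everything else —
per-category rate, contact and duration ranges, a mortality table rising
from ~1.2%/yr in early childhood to ~33%/yr above 95, curve peakedness —
is drawn once per seed from wide plausible ranges. The pyramid is an
exponential age profile with its decay rate solved (Brent's method) to hit
the under-five share, plus 2% age noise, rescaled to exactly 5,000.

What the generator does **not** emulate: correlation between task rates and
demography (a high-fertility region's diarrhea burden is drawn independently
of its pyramid), migration, age-dependent fertility *spreads*, real
seasonality shapes (curves are single-peaked von-Mises-like bumps), and any
specific region's true parameter vector. Consequently, passing tests show
the machinery is correct and the statistics behave as designed — not that
the synthetic magnitudes match any real catchment; absolute workload levels
from synthetic regions are illustrative only.

## Numerical choices and edge cases

* Curve normalization tolerance: 1e-9 at validation, 1e-6 at allocation
  (CSV round trips preserve full precision via `repr`, so the loose bound
  only catches genuinely broken inputs).
* Rates are clamped into [0, 1] after each year's change multiplication;
  mortality likewise. Change ratios must be strictly positive.
* A task that is seasonal but supplies no offsets defaults to all-zero
  offsets (every contact at the curve's own timing).
* Degenerate inputs raise: empty trial sets, all-zero months in the
  peak-month ratio, non-positive populations in per-capita conversion,
  mortality above 1, negative spreads.
* Problem sizes: headline runs use 100 trials over 16 years with ~72 tasks
  (a few seconds per scenario); the age-tracked runs use 50 trials. These
  sizes put Monte Carlo standard errors on the median well inside the
  percentile bands being reported.

## Known limitations

Rates are treated as independent of the demography they act on (declining
child mortality does not feed back into sick-child incidence); no
migration; annual time steps mean within-year dynamics exist only through
the seasonality curves; the fixed-catchment mode rescales rather than
modelling turnover; workload is demand (needed clinical time), not supply —
translating it into headcounts, rosters or costs is out of scope.
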