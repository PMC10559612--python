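"""Monte Carlo scenarios and cross-trial statistics.

A *scenario* couples a region parameter set with a population mode and a
sampling configuration, then simulates ``n_trials`` independent trajectories
from the start year to the end year. Each trial draws its own initial rates
(parameter uncertainty) and, every simulated year, fresh year-over-year
change ratios (trend stochasticity), projects the population forward, and
runs the task-time engine.

Population modes:

* ``growing`` — the catchment follows the projected pyramid;
* ``fixed_5000`` — after each projection step the pyramid is rescaled so the
  total is exactly the facility's nominal catchment (default 5,000) while the
  evolving age/sex shape is preserved. Comparing the two modes isolates the
  effect of population structure from total growth.

Cross-trial summaries report the median with 25-75 and 5-95 percentile bands
of annual hours, the peak-month-to-average ratio with a 90% interval, and
scenario comparisons (fertility-trend sensitivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import engine
from .demography import births_in_year, step_population
from .params import RegionParameters
from .stochastics import (
    SamplingConfig,
    sample_change_ratio,
    sample_initial_rate,
    trial_streams,
)

__all__ = [
    "ScenarioConfig",
    "TrialSet",
    "run_scenario",
    "summarize",
    "peak_month_ratio",
    "peak_ratio_summary",
    "percent_change",
    "weekly_hours",
    "fertility_sensitivity",
]

logger = logging.getLogger(__name__)

GROWING = "growing"
FIXED_5000 = "fixed_5000"


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce one simulation run."""

    region: RegionParameters
    population_mode: str = GROWING
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    #: per-band fertility annual-change ratios overriding the region's table
    #: (used for fertility-trend sensitivity variants); None = region values
    fertility_change_override: Mapping[str, float] | None = None
    start_year: int | None = None
    end_year: int | None = None
    fixed_total: float = 5000.0
    sex_ratio_female: float = 0.5
    #: also compute the per-age/sex attribution each trial-year (slower)
    track_age: bool = False

    def years(self) -> range:
        start = self.region.start_year if self.start_year is None else self.start_year
        end = self.region.end_year if self.end_year is None else self.end_year
        if start >= end:
            raise ValueError("start_year must precede end_year")
        return range(start, end + 1)


@dataclass
class TrialSet:
    """Per-trial outputs of one scenario, in tidy long form.

    ``annual``:    trial, year, task, category, minutes
    ``monthly``:   trial, year, month (1-12), category, minutes
    ``population``: trial, year, population, births
    ``by_age``:    trial, year, age_group, sex, minutes (None unless tracked)
    """

    config: ScenarioConfig
    annual: pd.DataFrame
    monthly: pd.DataFrame
    population: pd.DataFrame
    by_age: pd.DataFrame | None = None

    def annual_hours(self) -> pd.DataFrame:
        """Total clinical hours per (trial, year)."""
        out = (
            self.annual.groupby(["trial", "year"], sort=True)["minutes"]
            .sum()
            .div(60.0)
            .rename("hours")
            .reset_index()
        )
        return out

    def monthly_totals(self) -> pd.DataFrame:
        """Whole-catalog minutes per (trial, year, month)."""
        return (
            self.monthly.groupby(["trial", "year", "month"], sort=True)["minutes"]
            .sum()
            .reset_index()
        )


def _sorted_bands(schedule) -> list[str]:
    from .params import parse_band

    return sorted(schedule.bands, key=parse_band)


def run_scenario(config: ScenarioConfig) -> TrialSet:
    """Simulate every trial of a scenario; reproducible from the master seed."""
    if config.population_mode not in (GROWING, FIXED_5000):
        raise ValueError(f"unknown population mode {config.population_mode!r}")
    region = config.region
    sampling = config.sampling
    years = config.years()
    curves = region.curve_map()
    fert_bands = _sorted_bands(region.fertility)
    mort_bands = _sorted_bands(region.mortality)
    fert_change = dict(region.fertility.annual_change)
    if config.fertility_change_override is not None:
        fert_change.update(config.fertility_change_override)

    annual_rows: list[tuple] = []
    monthly_rows: list[tuple] = []
    pop_rows: list[tuple] = []
    age_frames: list[pd.DataFrame] = []

    streams = trial_streams(sampling.master_seed, sampling.n_trials)
    for trial, rng in enumerate(streams):
        # --- per-trial initial draws (parameter uncertainty) ---------------
        task_rate = {
            t.task_name: sample_initial_rate(
                t.rate, t.rate_spread, rng, sampling.rate_distribution, upper=1.0
            )
            for t in region.tasks
        }
        # time per contact is samplable with the same machinery; catalog
        # spread defaults to zero, so this is exact unless configured.
        task_minutes = {t.task_name: t.minutes_per_contact for t in region.tasks}
        fert = {
            b: sample_initial_rate(
                region.fertility.bands[b], region.fertility.spread_for(b),
                rng, sampling.rate_distribution,
            )
            for b in fert_bands
        }
        mort = {
            b: sample_initial_rate(
                region.mortality.bands[b], region.mortality.spread_for(b),
                rng, sampling.rate_distribution, upper=1.0,
            )
            for b in mort_bands
        }
        # per-trial change draws, reused every year unless redrawn
        if not sampling.redraw_change_each_year:
            fixed_changes = _draw_changes(region, fert_change, fert_bands,
                                          mort_bands, rng, sampling)

        pyramid = region.baseline_pyramid.copy()
        if config.population_mode == FIXED_5000:
            pyramid = pyramid.scaled_to(config.fixed_total)

        for year in years:
            if year != years.start:
                if sampling.redraw_change_each_year:
                    changes = _draw_changes(region, fert_change, fert_bands,
                                            mort_bands, rng, sampling)
                else:
                    changes = fixed_changes
                for name, ratio in changes["tasks"].items():
                    task_rate[name] = min(task_rate[name] * ratio, 1.0)
                for b, ratio in changes["fertility"].items():
                    fert[b] = fert[b] * ratio
                for b, ratio in changes["mortality"].items():
                    mort[b] = min(mort[b] * ratio, 1.0)
                pyramid = step_population(
                    pyramid, fert, mort, sex_ratio_female=config.sex_ratio_female
                )
                if config.population_mode == FIXED_5000:
                    pyramid = pyramid.scaled_to(config.fixed_total)

            births = births_in_year(pyramid, fert)
            aw = engine.annual_workload(
                region.tasks, pyramid, births, rates=task_rate, minutes=task_minutes
            )
            mw = engine.monthly_workload(region.tasks, aw.per_task, curves, year)

            cat_of = {t.task_name: t.service_category for t in region.tasks}
            for name, minutes in aw.per_task.items():
                annual_rows.append((trial, year, name, cat_of[name], minutes))
            for category, months in mw.per_category.items():
                for m in range(12):
                    monthly_rows.append((trial, year, m + 1, category, months[m]))
            pop_rows.append((trial, year, aw.population, births))

            if config.track_age:
                frame = engine.attribute_by_age(region.tasks, aw.per_task,
                                                pyramid, births)
                frame.insert(0, "year", year)
                frame.insert(0, "trial", trial)
                age_frames.append(frame)

        logger.info("trial %d/%d complete (%s mode)",
                    trial + 1, sampling.n_trials, config.population_mode)

    annual = pd.DataFrame(annual_rows,
                          columns=["trial", "year", "task", "category", "minutes"])
    monthly = pd.DataFrame(monthly_rows,
                           columns=["trial", "year", "month", "category", "minutes"])
    population = pd.DataFrame(pop_rows,
                              columns=["trial", "year", "population", "births"])
    by_age = pd.concat(age_frames, ignore_index=True) if age_frames else None
    return TrialSet(config=config, annual=annual, monthly=monthly,
                    population=population, by_age=by_age)


def _draw_changes(region, fert_change, fert_bands, mort_bands, rng, sampling):
    """One year's sampled change ratios for every task and rate band."""
    return {
        "tasks": {
            t.task_name: sample_change_ratio(
                t.annual_change, t.annual_change_spread, rng,
                sampling.change_distribution,
            )
            for t in region.tasks
        },
        "fertility": {
            b: sample_change_ratio(
                fert_change.get(b, 1.0), region.fertility.change_spread_for(b),
                rng, sampling.change_distribution,
            )
            for b in fert_bands
        },
        "mortality": {
            b: sample_change_ratio(
                region.mortality.annual_change.get(b, 1.0),
                region.mortality.change_spread_for(b),
                rng, sampling.change_distribution,
            )
            for b in mort_bands
        },
    }


# ---------------------------------------------------------------------------
# Cross-trial statistics
# ---------------------------------------------------------------------------


def summarize(
    trials: TrialSet, percentiles: Sequence[float] = (5, 25, 50, 75, 95)
) -> pd.DataFrame:
    """Order-statistic summary of total annual hours across trials.

    Returns one row per year with the mean and the requested percentiles
    (columns ``p5``, ``p25``, ...). Percentile columns are non-decreasing in
    the percentile by construction.
    """
    hours = trials.annual_hours()
    if hours.empty:
        raise ValueError("cannot summarize an empty trial set")
    grouped = hours.groupby("year")["hours"]
    out = grouped.mean().rename("mean").to_frame()
    for p in percentiles:
        out[f"p{p:g}"] = grouped.quantile(p / 100.0)
    return out.reset_index()


def peak_month_ratio(months: Sequence[float]) -> float:
    """Max monthly workload divided by the mean monthly workload (>= 1)."""
    m = np.asarray(months, dtype=float)
    if m.shape != (12,):
        raise ValueError("need exactly 12 monthly values")
    mean = m.mean()
    if mean <= 0:
        raise ValueError("peak-month ratio undefined for all-zero months")
    return float(m.max() / mean)


def peak_ratio_summary(trials: TrialSet, interval: float = 0.90) -> pd.DataFrame:
    """Per-year median and simulation interval of the peak-month ratio."""
    if not 0 < interval < 1:
        raise ValueError("interval must lie in (0, 1)")
    totals = trials.monthly_totals()
    ratios = (
        totals.groupby(["trial", "year"])["minutes"]
        .apply(lambda m: peak_month_ratio(m.to_numpy()))
        .rename("ratio")
        .reset_index()
    )
    lo = (1 - interval) / 2
    grouped = ratios.groupby("year")["ratio"]
    return pd.DataFrame({
        "year": grouped.median().index,
        "median": grouped.median().to_numpy(),
        "lower": grouped.quantile(lo).to_numpy(),
        "upper": grouped.quantile(1 - lo).to_numpy(),
    })


def percent_change(v_start: float, v_end: float) -> float:
    """Relative change from start to end, in percent."""
    if v_start <= 0:
        raise ValueError("v_start must be > 0")
    return 100.0 * (v_end - v_start) / v_start


def weekly_hours(annual_hours: float, workweeks: float = 48.0) -> float:
    """Convert annual hours to hours per workweek (default 48 workweeks/yr)."""
    if workweeks <= 0:
        raise ValueError("workweeks must be > 0")
    return annual_hours / workweeks


def fertility_sensitivity(
    base: ScenarioConfig,
    variants: Mapping[str, Mapping[str, float] | None],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Re-run a scenario under alternative fertility-trend tables.

    ``variants`` maps a variant name to a per-band table of fertility
    annual-change ratios (``None`` = the region's own table). All variants
    share the base configuration and master seed (common random numbers), so
    differences are attributable to the fertility assumption alone.

    Returns ``(summaries, comparison)``: per-variant yearly summaries, and a
    pairwise table of percent differences between end-year median hours.
    """
    if len(variants) < 2:
        raise ValueError("need at least two fertility variants to compare")
    summaries: dict[str, pd.DataFrame] = {}
    end_median: dict[str, float] = {}
    for name, table in variants.items():
        cfg = replace(base, fertility_change_override=table)
        summary = summarize(run_scenario(cfg))
        summaries[name] = summary
        end_year = summary["year"].max()
        end_median[name] = float(
            summary.loc[summary["year"] == end_year, "p50"].iloc[0]
        )

    names = list(variants)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({
                "variant_a": a,
                "variant_b": b,
                "end_year_median_a": end_median[a],
                "end_year_median_b": end_median[b],
                "pct_diff_b_vs_a": percent_change(end_median[a], end_median[b]),
            })
    return summaries, pd.DataFrame(rows)


def flat_decline_table(region: RegionParameters, annual_ratio: float = 0.995) -> dict[str, float]:
    """A benchmark fertility-trend table: the same mild decline in every band.

    The default ratio 0.995 encodes a 0.5%/yr decline.
    """
    if annual_ratio <= 0:
        raise ValueError("annual_ratio must be > 0")
    return {band: annual_ratio for band in region.fertility.bands}
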