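"""Task-time accounting: turn a service catalog plus a population into
clinical minutes.

The core identity, applied per task and summed over the catalog::

    minutes/year = relevant population x rate x contacts x minutes per contact

where the relevant population is either a standing cohort (by sex and age
bounds) or, for birth-linked services (antenatal, delivery, postnatal,
newborn care), the year's expected births.

Monthly allocation spreads each contact's minutes across the calendar year
along the task's seasonality curve, shifted by the contact's month offset;
offsets wrap modulo 12 (steady-state approximation), so annual totals are
conserved exactly for every curve/offset combination. Tasks without a curve
are spread evenly over the twelve months.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    ClinicalTask,
    PopulationPyramid,
    RelevantPopulationSpec,
    SeasonalityCurve,
)

__all__ = [
    "AGE_GROUPS",
    "AnnualWorkload",
    "MonthlyWorkload",
    "relevant_count",
    "expected_task_minutes",
    "annual_workload",
    "allocate_monthly",
    "monthly_workload",
    "attribute_by_age",
    "per_capita_minutes",
]

#: Reporting age groups: (label, low, high) inclusive.
AGE_GROUPS: tuple[tuple[str, int, int], ...] = (
    ("infants", 0, 0),
    ("under_5", 1, 4),
    ("5-14", 5, 14),
    ("15-24", 15, 24),
    ("25-34", 25, 34),
    ("35-44", 35, 44),
    ("45-54", 45, 54),
    ("55-64", 55, 64),
    ("65-100", 65, 100),
)

#: Maternal services (birth-linked tasks) are attributed to women of
#: reproductive age in the age/sex breakdown.
_MATERNAL_AGES = (15, 49)


@dataclass
class AnnualWorkload:
    """One year's clinical time, broken out by task and service category.

    ``total_minutes`` equals the sum over tasks; category minutes partition
    the total (both hold by construction in :func:`annual_workload`).
    """

    year: int
    per_task: dict[str, float]
    per_category: dict[str, float]
    total_minutes: float
    population: float

    @property
    def total_hours(self) -> float:
        return self.total_minutes / 60.0


@dataclass
class MonthlyWorkload:
    """One year's clinical minutes by calendar month (and per category)."""

    year: int
    months: np.ndarray  # shape (12,), whole-catalog minutes
    per_category: dict[str, np.ndarray]


def relevant_count(
    spec: RelevantPopulationSpec, pyramid: PopulationPyramid, births: float
) -> float:
    """Number of people a task applies to this year.

    Birth-linked specs return the year's expected births; general specs sum
    the pyramid over the spec's sex and inclusive age bounds.
    """
    if spec.birth_linked:
        return births
    return pyramid.count(spec.sex, spec.age_low, spec.age_high)


def expected_task_minutes(
    task: ClinicalTask,
    pyramid: PopulationPyramid,
    births: float,
    rate: float | None = None,
    minutes_per_contact: float | None = None,
) -> float:
    """Annual minutes for one task; sampled values override catalog values."""
    r = task.rate if rate is None else rate
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"sampled rate {r} outside [0, 1] for task {task.task_name!r}")
    m = task.minutes_per_contact if minutes_per_contact is None else minutes_per_contact
    n = relevant_count(task.relevant_population, pyramid, births)
    return n * r * task.num_contacts * m


def annual_workload(
    tasks: Sequence[ClinicalTask],
    pyramid: PopulationPyramid,
    births: float,
    rates: Mapping[str, float] | None = None,
    minutes: Mapping[str, float] | None = None,
) -> AnnualWorkload:
    """Sum the whole catalog into an :class:`AnnualWorkload`.

    ``rates`` / ``minutes`` optionally carry per-task sampled values keyed by
    task name; absent keys fall back to the catalog point estimates.
    """
    per_task: dict[str, float] = {}
    per_category: dict[str, float] = {}
    for task in tasks:
        m = expected_task_minutes(
            task,
            pyramid,
            births,
            rate=None if rates is None else rates.get(task.task_name),
            minutes_per_contact=None if minutes is None else minutes.get(task.task_name),
        )
        per_task[task.task_name] = per_task.get(task.task_name, 0.0) + m
        per_category[task.service_category] = (
            per_category.get(task.service_category, 0.0) + m
        )
    total = float(sum(per_task.values()))
    return AnnualWorkload(
        year=pyramid.year,
        per_task=per_task,
        per_category=per_category,
        total_minutes=total,
        population=pyramid.total(),
    )


def allocate_monthly(
    annual_minutes: float,
    curve: SeasonalityCurve | None,
    offset: int = 0,
) -> np.ndarray:
    """Spread an annual total over 12 months along a seasonality curve.

    Month ``m`` (0-based) receives ``annual * weight[(m - offset) % 12]``; a
    positive offset shifts demand later in the year. ``curve=None`` means no
    seasonality: demand is spread evenly. Raises on an unnormalized curve.
    """
    if curve is None:
        return np.full(12, annual_minutes / 12.0)
    w = curve.weights_array()
    if abs(float(w.sum()) - 1.0) > 1e-6:
        raise ValueError(
            f"seasonality curve {curve.curve_id!r} is not normalized "
            f"(sum {float(w.sum()):.9g})"
        )
    return annual_minutes * np.roll(w, offset)


def task_monthly_minutes(
    task: ClinicalTask,
    task_minutes: float,
    curves: Mapping[str, SeasonalityCurve],
) -> np.ndarray:
    """A task's minutes by month, each contact shifted by its own offset.

    Contacts carry equal time, so each receives an equal share of the task's
    annual minutes before allocation.
    """
    if task_minutes == 0.0 or task.num_contacts == 0:
        return np.zeros(12)
    curve = curves.get(task.seasonality_curve_id) if task.seasonality_curve_id else None
    if curve is None:
        return allocate_monthly(task_minutes, None)
    share = task_minutes / task.num_contacts
    out = np.zeros(12)
    for offset in task.offsets_or_default():
        out += allocate_monthly(share, curve, offset)
    return out


def monthly_workload(
    tasks: Sequence[ClinicalTask],
    per_task_minutes: Mapping[str, float],
    curves: Mapping[str, SeasonalityCurve],
    year: int,
) -> MonthlyWorkload:
    """Allocate every task's annual minutes to calendar months."""
    months = np.zeros(12)
    per_category: dict[str, np.ndarray] = {}
    for task in tasks:
        tm = task_monthly_minutes(task, per_task_minutes.get(task.task_name, 0.0), curves)
        months += tm
        if task.service_category in per_category:
            per_category[task.service_category] += tm
        else:
            per_category[task.service_category] = tm.copy()
    return MonthlyWorkload(year=year, months=months, per_category=per_category)


def _attribution_weights(
    spec: RelevantPopulationSpec, pyramid: PopulationPyramid
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized (female, male) per-age attribution weights for a task."""
    female = np.zeros(len(pyramid.female))
    male = np.zeros(len(pyramid.male))
    if spec.birth_linked:
        lo, hi = _MATERNAL_AGES
        female[lo : hi + 1] = pyramid.female[lo : hi + 1]
        return female, male
    sl = slice(spec.age_low, spec.age_high + 1)
    if spec.sex in ("female", "both"):
        female[sl] = pyramid.female[sl]
    if spec.sex in ("male", "both"):
        male[sl] = pyramid.male[sl]
    return female, male


def attribute_by_age(
    tasks: Sequence[ClinicalTask],
    per_task_minutes: Mapping[str, float],
    pyramid: PopulationPyramid,
    births: float,
) -> pd.DataFrame:
    """Distribute each task's minutes over its relevant population by cohort.

    Minutes are split proportionally to cohort counts within the task's
    relevant population (birth-linked services go to women aged 15-49), then
    aggregated to the reporting :data:`AGE_GROUPS` by sex. The grand total is
    preserved. Returns a tidy frame (age_group, sex, minutes).
    """
    acc_f = np.zeros(len(pyramid.female))
    acc_m = np.zeros(len(pyramid.male))
    for task in tasks:
        minutes = per_task_minutes.get(task.task_name, 0.0)
        if minutes == 0.0:
            continue
        wf, wm = _attribution_weights(task.relevant_population, pyramid)
        denom = wf.sum() + wm.sum()
        if denom <= 0:
            # nobody in the relevant population yet minutes > 0 cannot happen
            # for general tasks; for birth-linked it would need births with no
            # reproductive-age women. Spread evenly to keep totals conserved.
            acc_f += minutes / (2 * len(acc_f))
            acc_m += minutes / (2 * len(acc_m))
            continue
        acc_f += minutes * wf / denom
        acc_m += minutes * wm / denom

    rows = []
    for label, lo, hi in AGE_GROUPS:
        rows.append({"age_group": label, "sex": "female",
                     "minutes": float(acc_f[lo : hi + 1].sum())})
        rows.append({"age_group": label, "sex": "male",
                     "minutes": float(acc_m[lo : hi + 1].sum())})
    return pd.DataFrame(rows)


def per_capita_minutes(total_minutes: float, population: float) -> float:
    """Minutes of clinical time per person per year."""
    if population <= 0:
        raise ValueError("population must be > 0")
    return total_minutes / population
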