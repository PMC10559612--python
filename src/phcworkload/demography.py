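"""Cohort-component population projection at single-year resolution.

The projection advances a :class:`~phcworkload.params.PopulationPyramid` one
calendar year at a time under age-banded fertility and mortality rates.
Within a simulated year the order of operations is fixed:

1. births are computed from start-of-year female counts (exposure),
2. mortality is applied to every cohort,
3. survivors age by one year (age 100 is absorbing for one year, then exits;
   there is no 101+ bin),
4. the year's births enter at age 0, split by a sex ratio (default 0.5/0.5).

All stochasticity lives outside this module: the functions here are
deterministic in the (already sampled) rates they receive.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .params import MAX_AGE, PopulationPyramid, parse_band

__all__ = [
    "interpolate_to_single_year",
    "apply_annual_change",
    "births_in_year",
    "step_population",
]


def interpolate_to_single_year(
    banded_counts: Mapping[str, tuple[float, float]], year: int
) -> PopulationPyramid:
    """Spread age-banded (female, male) counts uniformly over single years.

    ``banded_counts`` maps band labels ("0-4") to (female, male) totals; the
    bands must lie within 0..100. Per-band totals are conserved exactly:
    each single-year age in a band of width *w* receives 1/*w* of the band.

    Raises ``ValueError`` on a negative band count.
    """
    female = np.zeros(MAX_AGE + 1)
    male = np.zeros(MAX_AGE + 1)
    for label, (f_count, m_count) in banded_counts.items():
        if f_count < 0 or m_count < 0:
            raise ValueError(f"negative count in band {label!r}")
        lo, hi = parse_band(label)
        if not 0 <= lo <= hi <= MAX_AGE:
            raise ValueError(f"band {label!r} outside ages 0..{MAX_AGE}")
        width = hi - lo + 1
        female[lo : hi + 1] += f_count / width
        male[lo : hi + 1] += m_count / width
    return PopulationPyramid(year, female, male)


def apply_annual_change(base: float, change_ratio: float, n_years: int) -> float:
    """Compound a rate forward: ``base * change_ratio**n_years``, floored at 0.

    ``change_ratio`` is the multiplicative year-over-year trend
    (1.0 = no change); ``n_years`` is a non-negative horizon.
    """
    if change_ratio <= 0:
        raise ValueError("change_ratio must be > 0")
    if n_years < 0:
        raise ValueError("n_years must be >= 0")
    return max(base * change_ratio ** n_years, 0.0)


def births_in_year(
    pyramid: PopulationPyramid, fertility: Mapping[str, float]
) -> float:
    """Expected births over the year: sum of band rate x women in band.

    ``fertility`` maps age-band labels to annual births per woman. Only female
    counts contribute.
    """
    births = 0.0
    for label, rate in fertility.items():
        if rate < 0:
            raise ValueError(f"negative fertility rate in band {label!r}")
        lo, hi = parse_band(label)
        births += rate * float(pyramid.female[lo : min(hi, MAX_AGE) + 1].sum())
    return births


def _mortality_array(mortality: Mapping[str, float]) -> np.ndarray:
    rates = np.zeros(MAX_AGE + 1)
    for label, rate in mortality.items():
        if rate < 0:
            raise ValueError(f"negative mortality rate in band {label!r}")
        if rate > 1:
            raise ValueError(f"mortality rate {rate} > 1 in band {label!r}")
        lo, hi = parse_band(label)
        rates[lo : min(hi, MAX_AGE) + 1] = rate
    return rates


def step_population(
    pyramid: PopulationPyramid,
    fertility: Mapping[str, float],
    mortality: Mapping[str, float],
    sex_ratio_female: float = 0.5,
) -> PopulationPyramid:
    """Project the pyramid to the next calendar year.

    ``fertility`` and ``mortality`` are already-sampled annual rates by age
    band. Returns a new pyramid for ``pyramid.year + 1``; the input is not
    modified. See the module docstring for the within-year order of
    operations.
    """
    if not 0.0 <= sex_ratio_female <= 1.0:
        raise ValueError("sex_ratio_female must lie in [0, 1]")
    births = births_in_year(pyramid, fertility)
    q = _mortality_array(mortality)

    surv_f = pyramid.female * (1.0 - q)
    surv_m = pyramid.male * (1.0 - q)

    female = np.zeros(MAX_AGE + 1)
    male = np.zeros(MAX_AGE + 1)
    female[1:] = surv_f[:-1]  # survivors at age 100 exit the model
    male[1:] = surv_m[:-1]
    female[0] = births * sex_ratio_female
    male[0] = births * (1.0 - sex_ratio_female)
    return PopulationPyramid(pyramid.year + 1, female, male)
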