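"""Synthetic region parameter sets with realistic statistical structure.

Real regional inputs (task rates, fertility/mortality schedules, seasonality
curves) are not distributed with this package; this module generates complete,
validator-clean stand-ins from seeded archetypes so the full pipeline can be
exercised end to end. The magnitudes are drawn from wide plausible ranges
anchored to a handful of published reference points — e.g. urban fertility of
about 0.1 births/woman/yr at ages 20-24 and rising, versus rural fertility of
about 0.235 and declining; a 41.5%-style under-five malnutrition treatment
rate; a 2% annual decline for infectious-disease incidence — but no generated
set claims to reproduce any specific region's true parameter vector.

Archetypes:

* ``urban_low_fertility_rising``      — low fertility, upward trend, older
  pyramid (about 8% under five), weak seasonality;
* ``rural_high_fertility_declining``  — high fertility, downward trend, young
  pyramid (about 15% under five), strong seasonality;
* ``pastoral_high_fertility``         — highest fertility, roughly flat trend,
  young pyramid (about 11% under five), strong seasonality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import (
    FERTILITY_BANDS,
    MAX_AGE,
    SERVICE_CATEGORIES,
    ClinicalTask,
    PopulationPyramid,
    RateSchedule,
    RegionParameters,
    RelevantPopulationSpec,
    SeasonalityCurve,
    band_label,
)

__all__ = [
    "RegionArchetype",
    "ARCHETYPES",
    "generate_region",
    "generate_catalog",
    "generate_seasonality",
    "generate_pyramid",
]

#: Default catalog size: a comprehensive primary-care service package.
DEFAULT_N_TASKS = 72

#: Year-over-year ratio for infectious-disease incidence: 2% annual decline.
INFECTIOUS_DECLINE = 0.98

#: Curves available to seasonal conditions (births drive pregnancy services).
CURVE_IDS = ("births", "malaria", "malnutrition", "diarrhea", "tb")

_SEASONAL_CATEGORY_CURVE = {
    "malaria": "malaria",
    "nutrition": "malnutrition",
    "sick_child": "diarrhea",
    "tb": "tb",
}


@dataclass(frozen=True)
class RegionArchetype:
    """A named family of synthetic regions sharing demographic structure."""

    name: str
    #: baseline annual fertility per woman by 5-year band, ages 15-49
    fertility_base: dict[str, float]
    #: year-over-year fertility ratio by band
    fertility_change: dict[str, float]
    #: relative jitter applied to fertility levels (kept small so archetype
    #: anchors — e.g. the 20-24 band level — stay in their stated windows)
    fertility_jitter: float
    #: sampling weights over the 12 service categories
    category_weights: dict[str, float] = field(default_factory=dict)
    #: 0 = flat curves, 1 = strongly peaked
    seasonality_strength: float = 0.6
    #: target share of the 2020 population aged under five
    under_five_share: float = 0.14

    def __post_init__(self) -> None:
        if not 0.0 <= self.seasonality_strength <= 1.0:
            raise ValueError("seasonality_strength must lie in [0, 1]")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be >= 0")


def _fert(levels: list[float]) -> dict[str, float]:
    return {band: lvl for band, lvl in zip(FERTILITY_BANDS, levels)}


ARCHETYPES: dict[str, RegionArchetype] = {
    "urban_low_fertility_rising": RegionArchetype(
        name="urban_low_fertility_rising",
        fertility_base=_fert([0.015, 0.100, 0.120, 0.095, 0.055, 0.020, 0.005]),
        fertility_change={b: r for b, r in zip(
            FERTILITY_BANDS, [1.010, 1.012, 1.010, 1.008, 1.006, 1.004, 1.002])},
        fertility_jitter=0.08,
        category_weights={
            "family_planning": 1.6, "nutrition": 0.7, "pregnancy": 1.0,
            "sick_child": 0.9, "ncds": 2.0, "malaria": 0.2, "ntds": 0.3,
            "sexual_health": 1.0, "first_aid": 0.6, "tb": 0.6, "hiv": 0.8,
            "mental_health": 0.8,
        },
        seasonality_strength=0.3,
        under_five_share=0.08,
    ),
    "rural_high_fertility_declining": RegionArchetype(
        name="rural_high_fertility_declining",
        fertility_base=_fert([0.080, 0.235, 0.250, 0.210, 0.150, 0.070, 0.020]),
        fertility_change={b: r for b, r in zip(
            FERTILITY_BANDS, [0.985, 0.980, 0.982, 0.984, 0.986, 0.988, 0.990])},
        fertility_jitter=0.06,
        category_weights={
            "family_planning": 1.0, "nutrition": 1.6, "pregnancy": 1.4,
            "sick_child": 1.8, "ncds": 1.0, "malaria": 1.2, "ntds": 0.8,
            "sexual_health": 0.8, "first_aid": 0.6, "tb": 0.7, "hiv": 0.5,
            "mental_health": 0.4,
        },
        seasonality_strength=0.7,
        under_five_share=0.15,
    ),
    "pastoral_high_fertility": RegionArchetype(
        name="pastoral_high_fertility",
        fertility_base=_fert([0.095, 0.270, 0.280, 0.240, 0.170, 0.085, 0.025]),
        fertility_change={b: r for b, r in zip(
            FERTILITY_BANDS, [1.002, 1.000, 0.999, 0.999, 1.000, 1.001, 1.000])},
        fertility_jitter=0.05,
        category_weights={
            "family_planning": 0.7, "nutrition": 2.0, "pregnancy": 1.5,
            "sick_child": 1.6, "ncds": 0.8, "malaria": 1.4, "ntds": 1.0,
            "sexual_health": 0.7, "first_aid": 0.7, "tb": 0.8, "hiv": 0.4,
            "mental_health": 0.3,
        },
        seasonality_strength=0.8,
        under_five_share=0.11,
    ),
}


# ---------------------------------------------------------------------------
# Pyramid
# ---------------------------------------------------------------------------


def generate_pyramid(
    under_five_share: float,
    rng: np.random.Generator,
    total: float = 5000.0,
    year: int = 2020,
) -> PopulationPyramid:
    """A smooth young-age-heavy pyramid hitting an under-five share target.

    The age profile is exponential, ``n(a) ~ exp(-r a)``, with the decay rate
    solved so ages 0-4 carry ``under_five_share`` of the total before jitter;
    2% multiplicative age noise is added and the pyramid rescaled to
    ``total`` exactly.
    """
    if not 0.01 <= under_five_share <= 0.30:
        raise ValueError("under_five_share outside the plausible range [0.01, 0.30]")
    ages = np.arange(MAX_AGE + 1)

    def share(r: float) -> float:
        w = np.exp(-r * ages)
        return float(w[:5].sum() / w.sum()) - under_five_share

    r = brentq(share, 1e-6, 0.5)
    shape = np.exp(-r * ages)
    female = shape * 0.5 * (1.0 + 0.02 * rng.standard_normal(MAX_AGE + 1))
    male = shape * 0.5 * (1.0 + 0.02 * rng.standard_normal(MAX_AGE + 1))
    female = np.clip(female, 0.0, None)
    male = np.clip(male, 0.0, None)
    return PopulationPyramid(year, female, male).scaled_to(total)


# ---------------------------------------------------------------------------
# Seasonality
# ---------------------------------------------------------------------------


def generate_seasonality(
    curve_ids: tuple[str, ...] | list[str],
    strength: float,
    rng: np.random.Generator,
) -> list[SeasonalityCurve]:
    """One normalized 12-month curve per id.

    Each curve mixes a uniform floor with a circular (von-Mises-like) bump at
    a random peak month: ``strength = 0`` yields exactly uniform curves;
    ``strength = 1`` yields a strongly peaked curve whose maximum weight is
    at least twice the uniform level.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    months = np.arange(12)
    curves = []
    for cid in curve_ids:
        if strength == 0.0:
            weights = np.full(12, 1.0 / 12.0)
        else:
            peak = rng.integers(0, 12)
            kappa = 1.0 + 1.5 * strength
            bump = np.exp(kappa * np.cos(2 * np.pi * (months - peak) / 12.0))
            bump /= bump.sum()
            weights = (1.0 - strength) / 12.0 + strength * bump
            weights /= weights.sum()
        curves.append(SeasonalityCurve(curve_id=cid, weights=tuple(float(w) for w in weights)))
    return curves


# ---------------------------------------------------------------------------
# Task catalog
# ---------------------------------------------------------------------------

# per-category templates: (rate range, contacts range, minutes range,
# annual change range, population spec factory)
_CATEGORY_TEMPLATES = {
    "family_planning": ((0.10, 0.60), (1, 4), (5, 15), (1.000, 1.020),
                        lambda: RelevantPopulationSpec("female", 15, 49)),
    "nutrition": ((0.05, 0.45), (1, 3), (4, 12), (INFECTIOUS_DECLINE, INFECTIOUS_DECLINE),
                  lambda: RelevantPopulationSpec("both", 0, 4)),
    "sick_child": ((0.10, 0.60), (1, 3), (5, 15), (INFECTIOUS_DECLINE, INFECTIOUS_DECLINE),
                   lambda: RelevantPopulationSpec("both", 0, 4)),
    "ncds": ((0.01, 0.20), (1, 4), (6, 20), (1.005, 1.020),
             lambda: RelevantPopulationSpec("both", 25, 100)),
    "malaria": ((0.01, 0.30), (1, 2), (5, 15), (INFECTIOUS_DECLINE, INFECTIOUS_DECLINE),
                lambda: RelevantPopulationSpec("both", 0, 100)),
    "ntds": ((0.005, 0.10), (1, 2), (5, 12), (INFECTIOUS_DECLINE, INFECTIOUS_DECLINE),
             lambda: RelevantPopulationSpec("both", 0, 100)),
    "sexual_health": ((0.01, 0.15), (1, 2), (5, 15), (0.995, 1.005),
                      lambda: RelevantPopulationSpec("both", 15, 49)),
    "first_aid": ((0.01, 0.10), (1, 1), (5, 20), (0.995, 1.005),
                  lambda: RelevantPopulationSpec("both", 0, 100)),
    "tb": ((0.001, 0.010), (1, 4), (5, 15), (INFECTIOUS_DECLINE, INFECTIOUS_DECLINE),
           lambda: RelevantPopulationSpec("both", 5, 100)),
    "hiv": ((0.002, 0.050), (1, 4), (5, 15), (0.985, 0.995),
            lambda: RelevantPopulationSpec("both", 15, 49)),
    "mental_health": ((0.005, 0.050), (1, 3), (10, 25), (1.000, 1.010),
                      lambda: RelevantPopulationSpec("both", 15, 100)),
    "pregnancy": ((0.01, 0.15), (1, 2), (5, 20), (0.995, 1.005),
                  lambda: RelevantPopulationSpec("female", state="birth_linked")),
}

#: Core maternal/newborn tasks present in every catalog. Antenatal care has
#: four contacts at negative offsets (visits precede the birth along the
#: birth-seasonality curve); newborn immunization contacts trail it.
_CORE_BIRTH_TASKS = (
    ("antenatal_care_visits", 1.0, 4, (-6, -4, -2, -1), 12.0),
    ("facility_delivery", 0.9, 1, (0,), 60.0),
    ("postnatal_care", 0.85, 2, (0, 1), 15.0),
    ("newborn_immunization_series", 0.9, 3, (0, 1, 2), 8.0),
)


def generate_catalog(
    archetype: RegionArchetype,
    n_tasks: int,
    rng: np.random.Generator,
    seasonal: bool = True,
) -> list[ClinicalTask]:
    """A catalog of ``n_tasks`` tasks spanning the 12 service categories.

    Always includes the core birth-linked maternal/newborn tasks; remaining
    tasks are drawn by archetype category weights from per-category plausible
    ranges. Infectious-disease tasks carry the default 2%/yr declining trend
    and, when the archetype is seasonal, a condition-specific curve.
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    tasks: list[ClinicalTask] = []
    birth_spec = RelevantPopulationSpec("female", state="birth_linked")
    for name, rate, contacts, offsets, minutes in _CORE_BIRTH_TASKS[: max(n_tasks, 1)]:
        tasks.append(ClinicalTask(
            task_name=name,
            service_category="pregnancy",
            relevant_population=birth_spec,
            rate=rate,
            rate_kind="incidence",
            rate_spread=0.02,
            num_contacts=contacts,
            minutes_per_contact=minutes,
            annual_change=1.0,
            annual_change_spread=0.005,
            seasonality_curve_id="births" if seasonal else None,
            contact_offsets=offsets if seasonal else (),
        ))

    weights = np.array(
        [archetype.category_weights.get(c, 1.0) for c in SERVICE_CATEGORIES],
        dtype=float,
    )
    weights /= weights.sum()
    counters: dict[str, int] = {}
    while len(tasks) < n_tasks:
        category = str(rng.choice(SERVICE_CATEGORIES, p=weights))
        (r_lo, r_hi), (c_lo, c_hi), (m_lo, m_hi), (a_lo, a_hi), spec_fn = \
            _CATEGORY_TEMPLATES[category]
        counters[category] = counters.get(category, 0) + 1
        contacts = int(rng.integers(c_lo, c_hi + 1))
        rate = float(rng.uniform(r_lo, r_hi))
        curve = _SEASONAL_CATEGORY_CURVE.get(category) if seasonal else None
        if category == "pregnancy" and seasonal:
            curve = "births"
        tasks.append(ClinicalTask(
            task_name=f"{category}_task_{counters[category]:02d}",
            service_category=category,
            relevant_population=spec_fn(),
            rate=rate,
            rate_kind="prevalence" if category in ("ncds", "hiv", "mental_health")
                      else "incidence",
            rate_spread=float(rng.uniform(0.02, 0.10)) * rate,
            num_contacts=contacts,
            minutes_per_contact=float(rng.integers(m_lo, m_hi + 1)),
            annual_change=float(rng.uniform(a_lo, a_hi)),
            annual_change_spread=float(rng.uniform(0.002, 0.012)),
            seasonality_curve_id=curve,
            contact_offsets=tuple(range(contacts)) if curve else (),
        ))
    return tasks[:n_tasks]


# ---------------------------------------------------------------------------
# Schedules and full regions
# ---------------------------------------------------------------------------

# plausible annual mortality per person by 5-year band (higher in early
# childhood, rising steeply at old ages), jittered per region
_MORTALITY_BASE = {
    "0-4": 0.012, "5-9": 0.0018, "10-14": 0.0013, "15-19": 0.0018,
    "20-24": 0.0025, "25-29": 0.0030, "30-34": 0.0034, "35-39": 0.0040,
    "40-44": 0.0050, "45-49": 0.0065, "50-54": 0.0090, "55-59": 0.0125,
    "60-64": 0.0180, "65-69": 0.0270, "70-74": 0.0420, "75-79": 0.0650,
    "80-84": 0.1000, "85-89": 0.1550, "90-94": 0.2300, "95-100": 0.3300,
}


def _fertility_schedule(archetype: RegionArchetype, rng: np.random.Generator) -> RateSchedule:
    bands, change, rspread, cspread = {}, {}, {}, {}
    for band in FERTILITY_BANDS:
        base = archetype.fertility_base[band]
        level = base * (1.0 + archetype.fertility_jitter * rng.uniform(-1.0, 1.0))
        ratio = archetype.fertility_change[band]
        # jitter the trend without letting it cross 1.0 (the archetype's
        # direction of change is part of its identity)
        if ratio > 1.0:
            ratio = float(rng.uniform(1.0 + 0.5 * (ratio - 1.0), ratio + 0.5 * (ratio - 1.0)))
        elif ratio < 1.0:
            ratio = float(rng.uniform(ratio - 0.5 * (1.0 - ratio), 1.0 - 0.5 * (1.0 - ratio)))
        bands[band] = level
        change[band] = ratio
        rspread[band] = 0.05 * level
        cspread[band] = 0.004
    return RateSchedule("fertility", bands, change, rspread, cspread)


def _mortality_schedule(rng: np.random.Generator) -> RateSchedule:
    bands, change, rspread, cspread = {}, {}, {}, {}
    for band, base in _MORTALITY_BASE.items():
        level = base * (1.0 + 0.10 * rng.uniform(-1.0, 1.0))
        bands[band] = level
        change[band] = float(rng.uniform(0.985, 0.998))  # slowly improving survival
        rspread[band] = 0.05 * level
        cspread[band] = 0.003
    return RateSchedule("mortality", bands, change, rspread, cspread)


def generate_region(
    archetype: RegionArchetype | str,
    seed: int,
    n_tasks: int = DEFAULT_N_TASKS,
    start_year: int = 2020,
    end_year: int = 2035,
    total_population: float = 5000.0,
) -> RegionParameters:
    """A complete, validator-clean region parameter set.

    Deterministic in ``(archetype, seed, n_tasks)``; the baseline pyramid
    totals ``total_population`` (default 5,000 — the nominal catchment of one
    primary-care facility) in ``start_year``.

    Raises ``KeyError`` for an unknown archetype name.
    """
    if isinstance(archetype, str):
        try:
            archetype = ARCHETYPES[archetype]
        except KeyError:
            raise KeyError(
                f"unknown archetype {archetype!r}; choose from {sorted(ARCHETYPES)}"
            ) from None
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    pyramid = generate_pyramid(archetype.under_five_share, rng,
                               total=total_population, year=start_year)
    fertility = _fertility_schedule(archetype, rng)
    mortality = _mortality_schedule(rng)
    seasonal = archetype.seasonality_strength > 0.0
    curves = generate_seasonality(CURVE_IDS, archetype.seasonality_strength, rng)
    tasks = generate_catalog(archetype, n_tasks, rng, seasonal=seasonal)

    return RegionParameters(
        region_name=f"{archetype.name}_seed{seed}",
        baseline_pyramid=pyramid,
        fertility=fertility,
        mortality=mortality,
        tasks=tasks,
        curves=curves,
        start_year=start_year,
        end_year=end_year,
    )
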