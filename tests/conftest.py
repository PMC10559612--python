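import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phcworkload.params import (
    MAX_AGE,
    ClinicalTask,
    PopulationPyramid,
    RateSchedule,
    RegionParameters,
    RelevantPopulationSpec,
    SeasonalityCurve,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pyramid(year: int = 2020, **age_counts) -> PopulationPyramid:
    """Pyramid builder: make_pyramid(female={0: 100, ...}, male={...})."""
    female = np.zeros(MAX_AGE + 1)
    male = np.zeros(MAX_AGE + 1)
    for age, n in age_counts.get("female", {}).items():
        female[age] = n
    for age, n in age_counts.get("male", {}).items():
        male[age] = n
    return PopulationPyramid(year, female, male)


def _normalized(weights) -> tuple[float, ...]:
    w = np.asarray(weights, dtype=float)
    return tuple(float(x) for x in w / w.sum())


@pytest.fixture
def tiny_region() -> RegionParameters:
    """A hand-built three-task region with a fully known closed form.

    Population: 1,000 under-five children (100 per single-year age and sex),
    1,000 women aged 20-24 (200 per age). Fertility 0.2 in the 20-24 band and
    zero elsewhere, so expected births are exactly 200/yr. All sampling
    spreads are zero and all change ratios are 1.0, so every Monte Carlo
    trial reduces to the same arithmetic:

        malnutrition   1,000 x 0.415 x 2 x  5 =  4,150 min/yr
        family plan.   1,000 x 0.500 x 1 x 10 =  5,000 min/yr
        antenatal        200 x 1.000 x 4 x 12 =  9,600 min/yr
        total                                   18,750 min/yr = 312.5 h/yr
    """
    female = np.zeros(MAX_AGE + 1)
    male = np.zeros(MAX_AGE + 1)
    female[0:5] = 100.0
    male[0:5] = 100.0
    female[20:25] = 200.0

    fertility = RateSchedule(
        kind="fertility",
        bands={f"{lo}-{lo + 4}": (0.2 if lo == 20 else 0.0) for lo in range(15, 50, 5)},
        annual_change={f"{lo}-{lo + 4}": 1.0 for lo in range(15, 50, 5)},
    )
    mortality = RateSchedule(
        kind="mortality",
        bands={"0-100": 0.0},
        annual_change={"0-100": 1.0},
    )
    curves = [
        SeasonalityCurve("Malnutrition", _normalized([1, 1, 2, 4, 6, 4, 2, 1, 1, 1, 1, 1])),
        SeasonalityCurve("births", _normalized([2, 2, 3, 4, 5, 5, 4, 3, 2, 2, 2, 2])),
    ]
    tasks = [
        ClinicalTask(
            task_name="moderate_malnutrition_treatment",
            service_category="nutrition",
            relevant_population=RelevantPopulationSpec("both", 0, 4),
            rate=0.415, num_contacts=2, minutes_per_contact=5.0,
            annual_change=0.98, seasonality_curve_id="Malnutrition",
            contact_offsets=(0, 1),
        ),
        ClinicalTask(
            task_name="family_planning_counseling",
            service_category="family_planning",
            relevant_population=RelevantPopulationSpec("female", 15, 49),
            rate=0.5, num_contacts=1, minutes_per_contact=10.0,
        ),
        ClinicalTask(
            task_name="antenatal_care",
            service_category="pregnancy",
            relevant_population=RelevantPopulationSpec("female", state="birth_linked"),
            rate=1.0, num_contacts=4, minutes_per_contact=12.0,
            seasonality_curve_id="births", contact_offsets=(-3, -2, -1, 0),
        ),
    ]
    return RegionParameters(
        region_name="tiny_synthetic",
        baseline_pyramid=PopulationPyramid(2020, female, male),
        fertility=fertility,
        mortality=mortality,
        tasks=tasks,
        curves=curves,
        start_year=2020,
        end_year=2035,
    )


#: Closed-form per-task minutes for tiny_region's start year.
TINY_EXPECTED = {
    "moderate_malnutrition_treatment": 1000 * 0.415 * 2 * 5.0,
    "family_planning_counseling": 1000 * 0.5 * 1 * 10.0,
    "antenatal_care": 200.0 * 1.0 * 4 * 12.0,
}


@pytest.fixture(scope="session")
def rural_region():
    from phcworkload.synth import generate_region

    return generate_region("rural_high_fertility_declining", seed=7)
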