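"""Task-time engine: the per-task product, catalog totals, monthly
allocation, age/sex attribution, per-capita conversion."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phcworkload.engine import (
    allocate_monthly,
    annual_workload,
    attribute_by_age,
    expected_task_minutes,
    monthly_workload,
    per_capita_minutes,
    relevant_count,
    task_monthly_minutes,
)
from phcworkload.params import (
    ClinicalTask,
    RelevantPopulationSpec,
    SeasonalityCurve,
)

from .conftest import TINY_EXPECTED, make_pyramid


def simple_task(**overrides) -> ClinicalTask:
    base = dict(
        task_name="t",
        service_category="nutrition",
        relevant_population=RelevantPopulationSpec("both", 0, 4),
        rate=0.415,
        num_contacts=2,
        minutes_per_contact=5.0,
    )
    base.update(overrides)
    return ClinicalTask(**base)


class TestRelevantCount:
    def test_general_spec_sums_matching_cohorts(self):
        pyr = make_pyramid(female={20: 700, 30: 500, 60: 100}, male={25: 400})
        spec = RelevantPopulationSpec("female", 15, 49)
        assert relevant_count(spec, pyr, births=0.0) == 1200.0

    def test_birth_linked_spec_returns_births(self):
        pyr = make_pyramid(female={20: 700})
        spec = RelevantPopulationSpec("female", state="birth_linked")
        assert relevant_count(spec, pyr, births=180.0) == 180.0

    def test_both_sexes_is_sum_of_each(self):
        pyr = make_pyramid(female={2: 30, 3: 20}, male={2: 25})
        both = relevant_count(RelevantPopulationSpec("both", 0, 4), pyr, 0.0)
        f = relevant_count(RelevantPopulationSpec("female", 0, 4), pyr, 0.0)
        m = relevant_count(RelevantPopulationSpec("male", 0, 4), pyr, 0.0)
        assert both == f + m == 75.0


class TestTaskMinutes:
    def test_product_of_printed_factors(self):
        """1,000 under-five children x 0.415 x 2 contacts x 5 min = 4,150."""
        pyr = make_pyramid(
            female={a: 100 for a in range(5)}, male={a: 100 for a in range(5)}
        )
        assert expected_task_minutes(simple_task(), pyr, 0.0) == pytest.approx(
            4150.0, rel=1e-12
        )

    @pytest.mark.parametrize("kwargs", [{"rate": 0.0}, {"num_contacts": 0}])
    def test_zero_factors_give_zero_minutes(self, kwargs):
        pyr = make_pyramid(female={2: 100})
        assert expected_task_minutes(simple_task(**kwargs), pyr, 0.0) == 0.0

    def test_sampled_rate_overrides_catalog_rate(self):
        pyr = make_pyramid(female={2: 100})
        assert expected_task_minutes(simple_task(), pyr, 0.0, rate=0.1) == pytest.approx(
            100 * 0.1 * 2 * 5
        )

    def test_out_of_range_sampled_rate_rejected(self):
        pyr = make_pyramid(female={2: 100})
        with pytest.raises(ValueError):
            expected_task_minutes(simple_task(), pyr, 0.0, rate=1.5)

    def test_monotone_in_every_factor(self):
        pyr = make_pyramid(female={2: 100})
        bigger_pop = make_pyramid(female={2: 150})
        base = expected_task_minutes(simple_task(), pyr, 0.0)
        assert expected_task_minutes(simple_task(rate=0.5), pyr, 0.0) >= base
        assert expected_task_minutes(simple_task(num_contacts=3), pyr, 0.0) >= base
        assert expected_task_minutes(simple_task(minutes_per_contact=9.0), pyr, 0.0) >= base
        assert expected_task_minutes(simple_task(), bigger_pop, 0.0) >= base


class TestAnnualWorkload:
    def test_totals_and_hours(self, tiny_region):
        pyr = tiny_region.baseline_pyramid
        aw = annual_workload(tiny_region.tasks[:2], pyr, births=0.0)
        assert aw.total_minutes == pytest.approx(4150.0 + 5000.0)
        # two tasks of 4,150 and 850 minutes -> 5,000 minutes = 83.33 hours
        small = dataclasses.replace(tiny_region.tasks[1], rate=0.085)
        aw2 = annual_workload([tiny_region.tasks[0], small], pyr, births=0.0)
        assert aw2.total_minutes == pytest.approx(5000.0, rel=1e-12)
        assert aw2.total_hours == pytest.approx(83.3333333333, rel=1e-9)

    def test_empty_catalog_is_zero_workload(self):
        aw = annual_workload([], make_pyramid(female={1: 10}), births=0.0)
        assert aw.total_minutes == 0.0 and aw.per_task == {}

    def test_category_totals_partition_grand_total(self, tiny_region):
        pyr = tiny_region.baseline_pyramid
        aw = annual_workload(tiny_region.tasks, pyr, births=200.0)
        assert sum(aw.per_category.values()) == pytest.approx(aw.total_minutes, rel=1e-12)
        assert sum(aw.per_task.values()) == pytest.approx(aw.total_minutes, rel=1e-12)
        for name, expected in TINY_EXPECTED.items():
            assert aw.per_task[name] == pytest.approx(expected, rel=1e-12)


class TestMonthlyAllocation:
    def test_uniform_curve_spreads_evenly(self):
        curve = SeasonalityCurve("flat", tuple([1 / 12] * 12))
        months = allocate_monthly(1200.0, curve, offset=5)
        assert np.allclose(months, 100.0)

    def test_point_mass_shifts_by_offset(self):
        w = [0.0] * 12
        w[2] = 1.0  # all demand in month 3
        curve = SeasonalityCurve("point", tuple(w))
        months = allocate_monthly(600.0, curve, offset=1)
        assert months[3] == 600.0 and months.sum() == 600.0

    def test_no_curve_means_even_distribution(self):
        months = allocate_monthly(1200.0, None)
        assert np.allclose(months, 100.0)

    def test_unnormalized_curve_rejected(self):
        bad = SeasonalityCurve("bad", tuple([0.2] * 12))
        with pytest.raises(ValueError, match="not normalized"):
            allocate_monthly(100.0, bad, 0)

    @given(
        raw=st.lists(st.floats(0.001, 10.0), min_size=12, max_size=12),
        offset=st.integers(-24, 24),
        annual=st.floats(0.0, 1e7),
    )
    def test_conservation_for_any_curve_and_offset(self, raw, offset, annual):
        w = np.asarray(raw) / np.sum(raw)
        curve = SeasonalityCurve("c", tuple(w))
        months = allocate_monthly(annual, curve, offset)
        assert months.sum() == pytest.approx(annual, rel=1e-9, abs=1e-9)
        assert (months >= 0).all()

    def test_per_contact_offsets_conserve_task_total(self, tiny_region):
        curves = tiny_region.curve_map()
        anc = tiny_region.tasks[2]
        months = task_monthly_minutes(anc, 9600.0, curves)
        assert months.sum() == pytest.approx(9600.0, rel=1e-12)

    def test_monthly_workload_matches_annual(self, tiny_region):
        pyr = tiny_region.baseline_pyramid
        aw = annual_workload(tiny_region.tasks, pyr, births=200.0)
        mw = monthly_workload(tiny_region.tasks, aw.per_task,
                              tiny_region.curve_map(), pyr.year)
        assert mw.months.sum() == pytest.approx(aw.total_minutes, rel=1e-9)
        for cat, months in mw.per_category.items():
            assert months.sum() == pytest.approx(aw.per_category[cat], rel=1e-9)


class TestAgeAttribution:
    def test_female_only_task_gives_males_nothing(self):
        pyr = make_pyramid(female={20: 100}, male={20: 100})
        task = simple_task(
            relevant_population=RelevantPopulationSpec("female", 15, 49)
        )
        frame = attribute_by_age([task], {"t": 1000.0}, pyr, births=0.0)
        assert frame.loc[frame.sex == "male", "minutes"].sum() == 0.0
        assert frame["minutes"].sum() == pytest.approx(1000.0)

    def test_proportional_split_between_infants_and_under_five(self):
        """200 infants and 800 children aged 1-4 -> a 20%/80% split."""
        pyr = make_pyramid(
            female={0: 100, 1: 200, 2: 200}, male={0: 100, 2: 200, 3: 200}
        )
        frame = attribute_by_age([simple_task()], {"t": 1000.0}, pyr, births=0.0)
        by_group = frame.groupby("age_group")["minutes"].sum()
        assert by_group["infants"] == pytest.approx(200.0)
        assert by_group["under_5"] == pytest.approx(800.0)

    def test_birth_linked_minutes_go_to_reproductive_age_women(self, tiny_region):
        pyr = tiny_region.baseline_pyramid
        frame = attribute_by_age(
            [tiny_region.tasks[2]], {"antenatal_care": 9600.0}, pyr, births=200.0
        )
        female_1524 = frame[(frame.age_group == "15-24") & (frame.sex == "female")]
        assert female_1524["minutes"].iloc[0] == pytest.approx(9600.0)
        assert frame.loc[frame.sex == "male", "minutes"].sum() == 0.0

    def test_grand_total_conserved_for_full_catalog(self, tiny_region):
        pyr = tiny_region.baseline_pyramid
        aw = annual_workload(tiny_region.tasks, pyr, births=200.0)
        frame = attribute_by_age(tiny_region.tasks, aw.per_task, pyr, births=200.0)
        assert frame["minutes"].sum() == pytest.approx(aw.total_minutes, rel=1e-12)


class TestPerCapita:
    def test_division(self):
        assert per_capita_minutes(300_000.0, 5000.0) == 60.0

    def test_zero_minutes(self):
        assert per_capita_minutes(0.0, 100.0) == 0.0

    def test_doubling_population_halves_per_capita(self):
        assert per_capita_minutes(100.0, 200.0) == per_capita_minutes(100.0, 100.0) / 2

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            per_capita_minutes(10.0, 0.0)
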