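"""Scenario runner and cross-trial statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from phcworkload.params import ClinicalTask, RelevantPopulationSpec
from phcworkload.scenarios import (
    ScenarioConfig,
    fertility_sensitivity,
    flat_decline_table,
    peak_month_ratio,
    peak_ratio_summary,
    percent_change,
    run_scenario,
    summarize,
    weekly_hours,
)
from phcworkload.stochastics import SamplingConfig

from .conftest import TINY_EXPECTED


def degenerate_config(region, n_trials=3, **kwargs):
    """Zero spreads are already baked into tiny_region's catalog; with all
    change ratios 1.0 (also baked in) the run is fully deterministic."""
    return ScenarioConfig(
        region=region,
        sampling=SamplingConfig(master_seed=5, n_trials=n_trials),
        **kwargs,
    )


class TestRunScenario:
    def test_degenerate_trials_are_identical_and_match_closed_form(self, tiny_region):
        ts = run_scenario(degenerate_config(tiny_region))
        start = tiny_region.start_year
        first_year = ts.annual[ts.annual.year == start]
        for trial in first_year.trial.unique():
            sub = first_year[first_year.trial == trial].set_index("task")["minutes"]
            for name, expected in TINY_EXPECTED.items():
                assert sub[name] == pytest.approx(expected, rel=1e-12)
        # all trials identical across every year
        pivot = ts.annual.pivot_table(index=["year", "task"], columns="trial",
                                      values="minutes")
        assert np.allclose(pivot.values, pivot.values[:, [0]], rtol=1e-12)

    def test_degenerate_all_ages_task_is_year_over_year_constant(self, tiny_region):
        """With zero fertility/mortality and no trends, an all-ages task's
        series is constant: the engine sees the same relevant population
        every year."""
        task = ClinicalTask(
            task_name="everyone", service_category="first_aid",
            relevant_population=RelevantPopulationSpec("both", 0, 100),
            rate=0.2, num_contacts=1, minutes_per_contact=10.0,
        )
        zero_fertility = dataclasses.replace(
            tiny_region.fertility,
            bands={b: 0.0 for b in tiny_region.fertility.bands},
        )
        region = dataclasses.replace(
            tiny_region, tasks=[task], fertility=zero_fertility
        )
        ts = run_scenario(degenerate_config(region, n_trials=2))
        series = ts.annual[ts.annual.trial == 0].set_index("year")["minutes"]
        assert np.allclose(series.values, series.values[0], rtol=1e-12)

    def test_fixed_mode_totals_exactly_5000_every_year(self, rural_region):
        cfg = ScenarioConfig(
            region=rural_region, population_mode="fixed_5000",
            sampling=SamplingConfig(master_seed=3, n_trials=2),
        )
        ts = run_scenario(cfg)
        assert np.allclose(ts.population["population"], 5000.0, rtol=1e-9)

    def test_growing_mode_population_grows_under_dominant_fertility(self, tiny_region):
        ts = run_scenario(degenerate_config(tiny_region, n_trials=1))
        pop = ts.population.sort_values("year")["population"].to_numpy()
        # zero mortality: totals never shrink, and they grow while the
        # initial mothers remain in the fertile band (they age out after
        # five years, so growth plateaus rather than continuing)
        assert (np.diff(pop) >= 0).all()
        assert (np.diff(pop[:5]) > 0).all()
        assert pop[-1] > pop[0]

    def test_identical_master_seed_bit_identical_outputs(self, rural_region):
        cfg = ScenarioConfig(
            region=rural_region,
            sampling=SamplingConfig(master_seed=11, n_trials=3),
        )
        a, b = run_scenario(cfg), run_scenario(cfg)
        pd.testing.assert_frame_equal(a.annual, b.annual)
        pd.testing.assert_frame_equal(a.monthly, b.monthly)
        pd.testing.assert_frame_equal(a.population, b.population)

    def test_unknown_mode_rejected(self, tiny_region):
        with pytest.raises(ValueError, match="population mode"):
            run_scenario(dataclasses.replace(
                degenerate_config(tiny_region), population_mode="shrinking"))


class TestSummaries:
    def test_known_order_statistics(self, tiny_region):
        """Trial totals 1..100 hours -> median 50.5 by linear interpolation."""
        rows = [
            {"trial": t, "year": 2020, "task": "x", "category": "ncds",
             "minutes": 60.0 * (t + 1)}
            for t in range(100)
        ]
        ts = run_scenario(degenerate_config(tiny_region, n_trials=1))
        ts.annual = pd.DataFrame(rows)
        out = summarize(ts)
        assert out.loc[0, "p50"] == pytest.approx(50.5)
        assert out.loc[0, "p5"] <= out.loc[0, "p25"] <= out.loc[0, "p50"]
        assert out.loc[0, "p50"] <= out.loc[0, "p75"] <= out.loc[0, "p95"]

    def test_identical_trials_zero_width_bands(self, tiny_region):
        ts = run_scenario(degenerate_config(tiny_region, n_trials=10))
        out = summarize(ts)
        assert np.allclose(out["p5"], out["p95"], rtol=1e-12)

    def test_percentile_ordering_for_stochastic_run(self, rural_region):
        cfg = ScenarioConfig(
            region=rural_region,
            sampling=SamplingConfig(master_seed=2, n_trials=20),
        )
        out = summarize(run_scenario(cfg))
        for lo, hi in [("p5", "p25"), ("p25", "p50"), ("p50", "p75"), ("p75", "p95")]:
            assert (out[lo] <= out[hi] + 1e-12).all()


class TestPeakMonthRatio:
    def test_uniform_months_ratio_one(self):
        assert peak_month_ratio([10.0] * 12) == pytest.approx(1.0)

    def test_single_seasonal_task_closed_form(self):
        """A month carrying 0.2 of the annual total -> 0.2 / (1/12) = 2.4."""
        months = [0.8 / 11] * 12
        months[4] = 0.2
        assert peak_month_ratio(months) == pytest.approx(2.4)

    def test_scale_invariance(self):
        months = list(np.linspace(1, 5, 12))
        assert peak_month_ratio([7 * m for m in months]) == pytest.approx(
            peak_month_ratio(months)
        )

    def test_all_zero_months_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            peak_month_ratio([0.0] * 12)

    def test_summary_interval_brackets_median(self, rural_region):
        cfg = ScenarioConfig(
            region=rural_region,
            sampling=SamplingConfig(master_seed=4, n_trials=15),
        )
        out = peak_ratio_summary(run_scenario(cfg))
        assert ((out["lower"] <= out["median"]) & (out["median"] <= out["upper"])).all()
        assert (out["median"] >= 1.0).all()


class TestReportingArithmetic:
    def test_percent_change(self):
        assert percent_change(2930.0, 3742.0) == pytest.approx(27.713, abs=1e-3)
        assert round(percent_change(2930.0, 3742.0)) == 28
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(100.0, 50.0) == -50.0
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)

    def test_weekly_hours(self):
        assert weekly_hours(3742.0) == pytest.approx(77.958, abs=1e-3)
        assert round(weekly_hours(3742.0)) == 78
        assert round(weekly_hours(2930.0)) == 61
        assert weekly_hours(0.0) == 0.0
        with pytest.raises(ValueError):
            weekly_hours(100.0, workweeks=0.0)


class TestFertilitySensitivity:
    def test_identical_variants_zero_difference(self, tiny_region):
        base = degenerate_config(tiny_region, n_trials=2)
        table = dict(tiny_region.fertility.annual_change)
        _, comparison = fertility_sensitivity(base, {"a": table, "b": table})
        assert comparison["pct_diff_b_vs_a"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_higher_fertility_weakly_higher_end_median(self, tiny_region):
        base = degenerate_config(tiny_region, n_trials=2)
        low = {band: 0.99 for band in tiny_region.fertility.bands}
        high = {band: 1.02 for band in tiny_region.fertility.bands}
        summaries, comparison = fertility_sensitivity(base, {"low": low, "high": high})
        assert comparison["pct_diff_b_vs_a"].iloc[0] >= 0.0
        end = summaries["high"]["year"].max()
        assert (
            summaries["high"].loc[summaries["high"].year == end, "p50"].iloc[0]
            >= summaries["low"].loc[summaries["low"].year == end, "p50"].iloc[0]
        )

    def test_three_variants_emit_three_pairwise_rows(self, tiny_region):
        base = degenerate_config(tiny_region, n_trials=1)
        tables = {
            "recent": {b: 1.01 for b in tiny_region.fertility.bands},
            "long_term": {b: 0.99 for b in tiny_region.fertility.bands},
            "flat_benchmark": flat_decline_table(tiny_region),
        }
        _, comparison = fertility_sensitivity(base, tables)
        assert len(comparison) == 3

    def test_flat_decline_default_is_half_percent(self, tiny_region):
        table = flat_decline_table(tiny_region)
        assert all(r == 0.995 for r in table.values())

    def test_fewer_than_two_variants_rejected(self, tiny_region):
        with pytest.raises(ValueError):
            fertility_sensitivity(degenerate_config(tiny_region), {"only": None})
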