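"""Scenario runner, cost-breakdown bookkeeping, and report rendering."""

import json

import pandas as pd
import pytest

from osteoburden.errors import ConfigurationError, ConsistencyError
from osteoburden.scenarios_report import (
    CostBreakdown,
    PipelineInputs,
    ScenarioSpec,
    inflate_to_2010,
    ltc_prevalence_cost,
    percent_share,
    physician_visit_cost,
    render_tables,
    run_all_scenarios,
    run_scenario,
)


@pytest.fixture(scope="module")
def inputs(discharge, ambulatory, population, code_map, schedule):
    return PipelineInputs(
        discharge=discharge,
        ambulatory=ambulatory,
        population=population,
        code_map=code_map,
        schedule=schedule,
    )


@pytest.fixture(scope="module")
def base_result(inputs):
    return run_scenario(ScenarioSpec("base"), inputs)


class TestPhysicianVisitCost:
    def test_zero_visits(self, schedule):
        assert physician_visit_cost(0, 0.81, schedule) == 0.0

    def test_single_gp_visit_is_mean_of_fee_pair(self, schedule):
        assert physician_visit_cost(1, 1.0, schedule) == pytest.approx(49.225)

    def test_reported_visit_volume_reproduces_component(self, schedule):
        got = physician_visit_cost(2_370_000, 0.81, schedule)
        assert got == pytest.approx(143e6, rel=0.005)

    def test_share_outside_unit_interval_rejected(self, schedule):
        with pytest.raises(ValueError):
            physician_visit_cost(10, 1.2, schedule)


class TestInflation:
    def test_same_year_identity(self):
        assert inflate_to_2010(100.0, 2010, {2010: 116.5}) == 100.0

    def test_ratio_applied(self):
        assert inflate_to_2010(100.0, 2008, {2008: 100.0, 2010: 105.0}) == pytest.approx(105.0)

    def test_zero_amount(self):
        assert inflate_to_2010(0.0, 2008, {2008: 100.0, 2010: 105.0}) == 0.0

    def test_missing_year_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            inflate_to_2010(1.0, 1999, {2010: 116.5})


class TestLtcPrevalenceCost:
    def test_zero_prevalence(self, schedule):
        got = ltc_prevalence_cost({"F": 1e6, "M": 1e6}, {"F": 0, "M": 0}, schedule)
        assert got == 0.0

    def test_single_resident_year(self, schedule):
        got = ltc_prevalence_cost({"F": 1.0}, {"F": 1.0}, schedule)
        assert got == pytest.approx(53_936.05)

    def test_reported_resident_stock(self, schedule):
        # 30,425 attributable residents for a full year at $147.77/day
        got = ltc_prevalence_cost(
            {"F": 112_500.0, "M": 40_000.0}, {"F": 0.21, "M": 0.17}, schedule
        )
        assert got == pytest.approx(1.641e9, rel=0.005)

    def test_invalid_prevalence_rejected(self, schedule):
        with pytest.raises(ConfigurationError):
            ltc_prevalence_cost({"F": 10.0}, {"F": 1.5}, schedule)


class TestCostBreakdown:
    def test_total_is_sum_of_components_to_the_cent(self):
        bd = CostBreakdown(acute=1.005, drugs=2.005)
        assert bd.total == pytest.approx(bd.acute + bd.drugs)
        bd.check()

    def test_tampered_component_raises_consistency_error(self):
        bd = CostBreakdown(acute=100.0)
        bd.acute = 200.0
        with pytest.raises(ConsistencyError):
            bd.check()

    def test_all_zero_components_total_zero(self):
        assert CostBreakdown().total == 0.0


class TestRunScenario:
    def test_unknown_scenario_name_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec("bogus")

    def test_base_total_equals_component_sum(self, base_result):
        bd = base_result.breakdown
        comps = [bd.acute, bd.rehabilitation, bd.continuing_care,
                 bd.long_term_care, bd.home_care, bd.physician, bd.drugs,
                 bd.indirect]
        assert bd.total == pytest.approx(sum(comps), abs=0.01)

    def test_all_trauma_dominates_base(self, inputs, base_result):
        at = run_scenario(ScenarioSpec("all_trauma"), inputs)
        assert at.breakdown.total >= base_result.breakdown.total
        assert at.counts["admissions_national"] >= base_result.counts[
            "admissions_national"
        ]

    def test_ltc_prevalence_dominates_base(self, inputs, base_result):
        ltc = run_scenario(ScenarioSpec("ltc_prevalence"), inputs)
        assert ltc.breakdown.total >= base_result.breakdown.total
        assert ltc.breakdown.long_term_care > base_result.breakdown.long_term_care

    def test_op_only_scenario_adds_admissions(self, inputs, base_result):
        op = run_scenario(ScenarioSpec("add_op_only_admissions", op_only_n=100.0), inputs)
        assert op.counts["admissions_national"] == pytest.approx(
            base_result.counts["admissions_national"] + 100.0
        )
        assert op.breakdown.acute > base_result.breakdown.acute
        # components untouched by the scenario inherit the base verbatim
        assert op.breakdown.home_care == base_result.breakdown.home_care
        assert op.breakdown.drugs == base_result.breakdown.drugs

    def test_replay_is_deterministic(self, inputs, base_result):
        again = run_scenario(ScenarioSpec("base"), inputs)
        assert again.breakdown.as_dict() == base_result.breakdown.as_dict()
        assert again.counts == base_result.counts

    def test_component_overrides_pin_values(self, inputs):
        spec = ScenarioSpec("base", overrides={"drugs": 12345.0})
        res = run_scenario(spec, inputs)
        assert res.breakdown.drugs == 12345.0
        assert res.overrides_applied == {"drugs": 12345.0}

    def test_all_components_overridden_to_zero(self, inputs):
        spec = ScenarioSpec(
            "base",
            overrides={c: 0.0 for c in (
                "acute", "rehabilitation", "continuing_care", "long_term_care",
                "home_care", "physician", "drugs", "indirect",
            )},
        )
        assert run_scenario(spec, inputs).breakdown.total == 0.0

    def test_attribute_then_extrapolate_matches_scaling_base_weights(self, inputs):
        # fractional weights commute with the linear extrapolation step:
        # halving every weight upstream halves national admission counts
        from dataclasses import replace

        from osteoburden.attribution import AttributionRates

        half = replace(
            inputs,
            rates=AttributionRates(other_site_rate_by_sex={"M": 0.3, "F": 0.3}),
        )
        full = replace(
            inputs,
            rates=AttributionRates(other_site_rate_by_sex={"M": 0.6, "F": 0.6}),
        )
        res_half = run_scenario(ScenarioSpec("base"), half)
        res_full = run_scenario(ScenarioSpec("base"), full)
        hv_half = res_half.site_counts.set_index("site")
        hv_full = res_full.site_counts.set_index("site")
        for site in ("wrist", "humerus", "other", "multiple"):
            if hv_full.loc[site, "hosp_national"] > 0:
                assert hv_half.loc[site, "hosp_national"] == pytest.approx(
                    0.5 * hv_full.loc[site, "hosp_national"]
                )


class TestRendering:
    def test_percent_rounding_half_away_from_zero(self):
        assert percent_share(622_840_008, 1_181_274_707) == 53
        assert percent_share(1_008_330_849, 1_181_274_707) == 85
        assert percent_share(5, 1000) == 1  # 0.5% rounds up, not to even

    def test_tables_written_and_consistent(self, inputs, tmp_path):
        results = run_all_scenarios(inputs)
        paths = render_tables(results, tmp_path)
        t4 = pd.read_csv(paths["table4.csv"])
        assert set(t4["cost_component"]) >= {"acute", "drugs", "total"}
        for name in results:
            col = t4.set_index("cost_component")[name]
            assert col["total"] == pytest.approx(
                col.drop("total").sum(), abs=0.05
            )
        t3 = pd.read_csv(paths["table3.csv"])
        body = t3[t3["fracture_type"] != "total"]
        assert body[["emergency_care", "acute_admissions", "day_surgery"]].sum(
            axis=1
        ).values == pytest.approx(body["total_acute_costs"].values)
        summary = json.loads(paths["summary.json"].read_text())
        assert summary["base"]["total"] == results["base"].breakdown.total

    def test_replaying_renders_identical_files(self, inputs, tmp_path):
        results = run_all_scenarios(inputs)
        p1 = render_tables(results, tmp_path / "a")
        p2 = render_tables(run_all_scenarios(inputs), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_empty_results_write_headers_only(self, tmp_path):
        paths = render_tables({}, tmp_path)
        t2 = pd.read_csv(paths["table2.csv"])
        assert len(t2) == 0

    def test_tampered_total_raises_at_render(self, inputs, tmp_path):
        results = {"base": run_scenario(ScenarioSpec("base"), inputs)}
        results["base"].breakdown.acute += 1.0
        with pytest.raises(ConsistencyError):
            render_tables(results, tmp_path)
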