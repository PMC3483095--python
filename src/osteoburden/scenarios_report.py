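"""Scenario runner and report rendering.

Assembles the eight-component cost breakdown (acute care, rehabilitation,
continuing care, long-term care, home care, physician visits, drugs,
indirect costs), runs the base case and the four sensitivity scenarios,
and renders the count/cost tables.

Scenarios:

``base``
    full pipeline: identify → attribute → cost → extrapolate.
``rocq_attribution``
    women's non-hip non-vertebral attribution uses age-specific Quebec
    cohort rates instead of the solved rate.
``add_op_only_admissions``
    adds admissions with osteoporosis alone (no fracture code) to the
    acute, rehabilitation and continuing-care components, pro-rated at
    the base per-admission component costs.
``ltc_prevalence``
    replaces the net-transfer long-term-care component with a
    prevalence-based cost over the stock of long-term-care residents
    attributable to osteoporosis.
``all_trauma``
    disables the severe-trauma exclusion and attributes every fracture
    in full.

Any of the eight components can be pinned to a literal value through the
override mechanism; applied overrides are recorded on the result and in
report footnotes. This is how report tables reproduce published
components whose exact inputs (mean post-acute RIWs, day-count splits)
were never published.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .acute_costing import SETTINGS, UnitCostSchedule, case_cost
from .attribution import AttributionRates, apply_attribution
from .care_pathways import (
    NetTransferSummary,
    PostAcuteParams,
    continuing_care_cost,
    homecare_cost,
    ltc_cost,
    rehab_cost,
)
from .case_identification import identify_cases
from .codes import SITE_CLASSES, TRANSFER_DESTINATIONS, CodeMap
from .errors import ConfigurationError, ConsistencyError
from .extrapolation import (
    extrapolate,
    extrapolated_total,
    population_by_stratum,
    scale_private_drug_claims,
    stratify,
)
from .indirect_costs import IndirectParams, caregiver_loss, productivity_loss

SCENARIO_NAMES = (
    "base",
    "rocq_attribution",
    "add_op_only_admissions",
    "ltc_prevalence",
    "all_trauma",
)

COMPONENTS = (
    "acute",
    "rehabilitation",
    "continuing_care",
    "long_term_care",
    "home_care",
    "physician",
    "drugs",
    "indirect",
)


def _cents(x: float) -> float:
    return round(float(x), 2)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class CostBreakdown:
    """Component-by-component costs in 2010 CAD (cent precision)."""

    acute: float = 0.0
    rehabilitation: float = 0.0
    continuing_care: float = 0.0
    long_term_care: float = 0.0
    home_care: float = 0.0
    physician: float = 0.0
    drugs: float = 0.0
    indirect: float = 0.0
    total: Optional[float] = None

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            setattr(self, name, _cents(getattr(self, name)))
        if self.total is None:
            self.total = _cents(sum(getattr(self, c) for c in COMPONENTS))

    def as_dict(self) -> dict[str, float]:
        d = {c: getattr(self, c) for c in COMPONENTS}
        d["total"] = self.total
        return d

    def check(self) -> None:
        expected = _cents(sum(getattr(self, c) for c in COMPONENTS))
        if abs(expected - self.total) > 0.005:
            raise ConsistencyError(
                f"total {self.total} != sum of components {expected}"
            )


@dataclass
class ScenarioSpec:
    """Named scenario plus its parameters and component overrides."""

    name: str = "base"
    op_only_n: float = 2096.0
    ltc_prevalence_male: float = 0.17
    ltc_prevalence_female: float = 0.21
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ConfigurationError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        for name in ("ltc_prevalence_male", "ltc_prevalence_female"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        bad = set(self.overrides) - set(COMPONENTS)
        if bad:
            raise ConfigurationError(f"overrides for unknown components: {sorted(bad)}")


@dataclass
class PipelineInputs:
    """Everything one scenario run needs.

    ``discharge`` and ``ambulatory`` are record tables in the generator's
    CSV layout. ``population`` covers every province (including ones with
    no records — that is what drives the extrapolation). Observed-input
    quantities with no record-level source (physician visits, drug
    spend, the long-term-care resident stock) enter as scalars.
    """

    discharge: pd.DataFrame
    ambulatory: pd.DataFrame
    population: pd.DataFrame
    code_map: CodeMap
    schedule: UnitCostSchedule = field(default_factory=UnitCostSchedule)
    rates: AttributionRates = field(default_factory=AttributionRates)
    postacute: PostAcuteParams = field(default_factory=PostAcuteParams)
    indirect: IndirectParams = field(default_factory=IndirectParams)
    discharge_provinces: Optional[tuple[str, ...]] = None
    ambulatory_provinces: Optional[tuple[str, ...]] = None
    physician_visits: float = 2_363_293.0
    physician_share_gp: float = 0.81
    drug_public_spend: float = 278_000_000.0
    drug_private_observed: float = 73_355_648.0
    private_claim_coverage: float = 0.65
    ltc_residents_over65_by_sex: dict[str, float] = field(
        default_factory=lambda: {"M": 40_000.0, "F": 112_500.0}
    )
    productivity_day_components: tuple[str, ...] = (
        "acute",
        "home_care",
        "rehabilitation",
        "continuing_care",
    )
    overrides: dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioResult:
    """A cost breakdown plus the counts behind it."""

    spec: ScenarioSpec
    breakdown: CostBreakdown
    counts: dict[str, float]
    net_transfers: dict[str, NetTransferSummary]
    site_counts: pd.DataFrame
    acute_matrix: pd.DataFrame
    overrides_applied: dict[str, float]
    detail: dict[str, float]


def physician_visit_cost(
    n_visits: float, share_gp: float, schedule: UnitCostSchedule
) -> float:
    """Outpatient physician cost under the 50/50 consult/repeat assumption.

    Visits split between general practice and internal medicine by
    ``share_gp``; within each specialty half the visits bill the
    consultation fee and half the repeat-consultation fee.
    """
    if n_visits < 0:
        raise ValueError("visit count must be >= 0")
    if not 0.0 <= share_gp <= 1.0:
        raise ValueError(f"share_gp must be in [0, 1], got {share_gp}")
    gp_fee = (schedule.gp_consult + schedule.gp_repeat) / 2.0
    im_fee = (schedule.im_consult + schedule.im_repeat) / 2.0
    return n_visits * (share_gp * gp_fee + (1.0 - share_gp) * im_fee)


def inflate_to_2010(amount: float, year: int, cpi_table: dict[int, float]) -> float:
    """Inflate an amount from ``year`` dollars to 2010 dollars by CPI ratio."""
    try:
        return amount * cpi_table[2010] / cpi_table[int(year)]
    except KeyError as exc:
        raise ConfigurationError(f"no CPI index for year {exc.args[0]}") from None


def ltc_prevalence_cost(
    pop_over65_by_sex: dict[str, float],
    prevalences: dict[str, float],
    schedule: UnitCostSchedule,
    days_per_year: float = 365.0,
) -> float:
    """Prevalence-based yearly long-term-care cost.

    ``pop_over65_by_sex`` is the per-sex denominator of long-term-care
    residents over 65; ``prevalences`` the fractions of that denominator
    resident because of an osteoporosis-related fracture. Each
    attributable resident is costed a full year at the daily rate.
    """
    total = 0.0
    for sex, pop in pop_over65_by_sex.items():
        prev = prevalences.get(sex, 0.0)
        if not 0.0 <= prev <= 1.0:
            raise ConfigurationError(f"prevalence for sex {sex!r} not in [0, 1]")
        if pop < 0:
            raise ValueError("population must be >= 0")
        total += pop * prev * schedule.ltc_cost_per_day * days_per_year
    return total


# ----------------------------------------------------------------------
# pipeline internals


def _national_total(cases, value, src_pop, tgt_pop) -> float:
    strat = stratify(cases, value)
    if len(strat) == 0:
        return 0.0
    return extrapolated_total(strat, src_pop, tgt_pop)


def _national_by_band(cases, value, src_pop, tgt_pop) -> dict[str, float]:
    strat = stratify(cases, value)
    if len(strat) == 0:
        return {}
    out = extrapolate(strat, src_pop, tgt_pop)
    return out.groupby("age_band")["value"].sum().to_dict()


def _national_net_transfer(adm, destination, src_pop, tgt_pop) -> NetTransferSummary:
    discharged_total = admitted_total = net_total = 0.0
    for sex in ("F", "M"):
        sub = adm[adm["sex"] == sex]
        d = _national_total(
            sub[sub["discharge_destination"] == destination], None, src_pop, tgt_pop
        )
        a = _national_total(
            sub[sub["admission_source"] == destination], None, src_pop, tgt_pop
        )
        discharged_total += d
        admitted_total += a
        net_total += max(0.0, d - a)
    return NetTransferSummary(destination, discharged_total, admitted_total, net_total)


def _run_pipeline(
    inputs: PipelineInputs,
    *,
    mode: str = "mackey",
    exclude_trauma: bool = True,
    force_full_attribution: bool = False,
) -> dict:
    cm = inputs.code_map
    cases_d = identify_cases(
        inputs.discharge, cm, setting="admission", exclude_trauma=exclude_trauma
    )
    cases_a = identify_cases(inputs.ambulatory, cm, exclude_trauma=exclude_trauma)
    cases = pd.concat([cases_d, cases_a], ignore_index=True)
    if force_full_attribution:
        cases = cases.copy()
        if len(cases):
            cases["attribution_weight"] = 1.0
    else:
        cases = apply_attribution(cases, inputs.rates, mode=mode)
    adm = cases[cases["setting"] == "admission"]
    amb = cases[cases["setting"] != "admission"]

    discharge_provinces = inputs.discharge_provinces or tuple(
        sorted(inputs.discharge["province"].unique())
        if len(inputs.discharge)
        else ()
    )
    ambulatory_provinces = inputs.ambulatory_provinces or tuple(
        sorted(inputs.ambulatory["province"].unique())
        if len(inputs.ambulatory)
        else ()
    )
    nat_pop = population_by_stratum(inputs.population)
    roc_pop = population_by_stratum(inputs.population, discharge_provinces)
    amb_pop = population_by_stratum(inputs.population, ambulatory_provinces)

    schedule = inputs.schedule
    adm_costs = (
        adm.apply(lambda r: case_cost(r, schedule), axis=1) if len(adm) else None
    )
    amb_costs = (
        amb.apply(lambda r: case_cost(r, schedule), axis=1) if len(amb) else None
    )

    admissions_observed = float(adm["attribution_weight"].sum())
    admissions_national = _national_total(adm, None, roc_pop, nat_pop)
    days_national = _national_total(adm, adm["los_days"], roc_pop, nat_pop)
    days_by_band = _national_by_band(adm, adm["los_days"], roc_pop, nat_pop)
    acute_admission_cost = _national_total(adm, adm_costs, roc_pop, nat_pop)

    er = amb[amb["setting"] == "ER"]
    sds = amb[amb["setting"] == "day_surgery"]
    er_national = _national_total(er, None, amb_pop, nat_pop)
    sds_national = _national_total(sds, None, amb_pop, nat_pop)
    er_cost = _national_total(
        er, amb_costs.loc[er.index] if amb_costs is not None else None,
        amb_pop, nat_pop,
    )
    sds_cost = _national_total(
        sds, amb_costs.loc[sds.index] if amb_costs is not None else None,
        amb_pop, nat_pop,
    )

    # site-level detail for the count and acute-cost tables
    site_rows = []
    acute_cells = []
    for site in SITE_CLASSES:
        a_site = adm[adm["site"] == site]
        site_rows.append(
            {
                "site": site,
                "hosp_observed_women": float(
                    a_site.loc[a_site["sex"] == "F", "attribution_weight"].sum()
                ),
                "hosp_observed_men": float(
                    a_site.loc[a_site["sex"] == "M", "attribution_weight"].sum()
                ),
                "hosp_national": _national_total(a_site, None, roc_pop, nat_pop),
                "days_national": _national_total(
                    a_site, a_site["los_days"], roc_pop, nat_pop
                ),
            }
        )
        cell = {"site": site}
        cell["admission"] = _cents(
            _national_total(
                a_site,
                adm_costs.loc[a_site.index] if adm_costs is not None else None,
                roc_pop, nat_pop,
            )
        )
        for setting, sub in (("ER", er), ("day_surgery", sds)):
            s_site = sub[sub["site"] == site]
            cell[setting] = _cents(
                _national_total(
                    s_site,
                    amb_costs.loc[s_site.index] if amb_costs is not None else None,
                    amb_pop, nat_pop,
                )
            )
        acute_cells.append(cell)
    site_counts = pd.DataFrame(site_rows)
    acute_matrix = pd.DataFrame(acute_cells).set_index("site")
    acute_matrix["total"] = acute_matrix[list(SETTINGS)].sum(axis=1)

    nets = {
        dest: _national_net_transfer(adm, dest, roc_pop, nat_pop)
        for dest in TRANSFER_DESTINATIONS
    }

    pa = inputs.postacute
    rehabilitation = rehab_cost(pa, schedule, net=nets["rehabilitation"].net)
    continuing = continuing_care_cost(
        nets["continuing_care"].net, pa.cc_mean_days, pa.cc_mean_riw, schedule
    )
    long_term = ltc_cost(nets["long_term_care"].net, pa.ltc_mean_days, schedule)
    if pa.homecare_recipients is not None:
        recipients = pa.homecare_recipients
    else:
        recipients = _national_total(
            adm[adm["discharge_destination"] == "home_with_homecare"],
            None, roc_pop, nat_pop,
        )
    home = homecare_cost(recipients, pa.homecare_mean_weeks, schedule)

    physician = physician_visit_cost(
        inputs.physician_visits, inputs.physician_share_gp, schedule
    )
    drugs = inputs.drug_public_spend + scale_private_drug_claims(
        inputs.drug_private_observed, inputs.private_claim_coverage
    )

    # productivity: acute days come banded; facility/home-care days are
    # spread over bands in proportion to national admissions per band
    adm_by_band = _national_by_band(adm, None, roc_pop, nat_pop)
    adm_total = sum(adm_by_band.values()) or 1.0
    extra_days = 0.0
    if "rehabilitation" in inputs.productivity_day_components:
        extra_days += (
            pa.rehab_total_days
            if pa.rehab_total_days is not None
            else nets["rehabilitation"].net * pa.rehab_mean_days
        )
    if "continuing_care" in inputs.productivity_day_components:
        extra_days += nets["continuing_care"].net * pa.cc_mean_days
    if "long_term_care" in inputs.productivity_day_components:
        extra_days += nets["long_term_care"].net * pa.ltc_mean_days
    if "home_care" in inputs.productivity_day_components:
        extra_days += recipients * pa.homecare_mean_weeks * 7.0
    prod_days = {
        band: (
            (days_by_band.get(band, 0.0)
             if "acute" in inputs.productivity_day_components else 0.0)
            + extra_days * adm_by_band.get(band, 0.0) / adm_total
        )
        for band in set(days_by_band) | set(adm_by_band)
    }
    productivity = productivity_loss(prod_days, inputs.indirect)
    caregiver = caregiver_loss(admissions_national, inputs.indirect)

    return {
        "components": {
            "acute": acute_admission_cost + er_cost + sds_cost,
            "rehabilitation": rehabilitation,
            "continuing_care": continuing,
            "long_term_care": long_term,
            "home_care": home,
            "physician": physician,
            "drugs": drugs,
            "indirect": productivity + caregiver,
        },
        "counts": {
            "admissions_observed": admissions_observed,
            "admissions_national": admissions_national,
            "hospitalized_days_national": days_national,
            "er_visits_national": er_national,
            "day_surgeries_national": sds_national,
            "homecare_recipients": recipients,
        },
        "net_transfers": nets,
        "site_counts": site_counts,
        "acute_matrix": acute_matrix,
        "detail": {"productivity": productivity, "caregiver": caregiver},
    }


def run_scenario(spec: ScenarioSpec, inputs: PipelineInputs) -> ScenarioResult:
    """Run one named scenario end to end and return its result."""
    if spec.name == "rocq_attribution":
        state = _run_pipeline(inputs, mode="rocq_women")
    elif spec.name == "all_trauma":
        state = _run_pipeline(
            inputs, exclude_trauma=False, force_full_attribution=True
        )
    else:
        state = _run_pipeline(inputs)

    components = state["components"]
    counts = state["counts"]

    if spec.name == "add_op_only_admissions":
        # osteoporosis-without-fracture admissions share the base
        # per-admission acute / rehab / continuing-care intensity
        base_adm = counts["admissions_national"]
        if base_adm > 0 and spec.op_only_n > 0:
            scale = 1.0 + spec.op_only_n / base_adm
            for comp in ("acute", "rehabilitation", "continuing_care"):
                components[comp] *= scale
            counts["admissions_national"] = base_adm + spec.op_only_n
    elif spec.name == "ltc_prevalence":
        components["long_term_care"] = ltc_prevalence_cost(
            inputs.ltc_residents_over65_by_sex,
            {"M": spec.ltc_prevalence_male, "F": spec.ltc_prevalence_female},
            inputs.schedule,
        )

    overrides = {**inputs.overrides, **spec.overrides}
    applied = {}
    for comp, value in overrides.items():
        applied[comp] = float(value)
        components[comp] = float(value)

    breakdown = CostBreakdown(**{c: components[c] for c in COMPONENTS})
    return ScenarioResult(
        spec=spec,
        breakdown=breakdown,
        counts=counts,
        net_transfers=state["net_transfers"],
        site_counts=state["site_counts"],
        acute_matrix=state["acute_matrix"],
        overrides_applied=applied,
        detail=state["detail"],
    )


def run_all_scenarios(
    inputs: PipelineInputs, specs: Optional[list[ScenarioSpec]] = None
) -> dict[str, ScenarioResult]:
    """Run the base case and every sensitivity scenario."""
    if specs is None:
        specs = [ScenarioSpec(name=n) for n in SCENARIO_NAMES]
    return {spec.name: run_scenario(spec, inputs) for spec in specs}


# ----------------------------------------------------------------------
# rendering


def percent_share(value: float, total: float) -> int:
    """Integer percent share, rounded half away from zero."""
    if total == 0:
        return 0
    return round_half_away(100.0 * value / total)


def render_tables(results: dict[str, ScenarioResult], outdir) -> dict[str, Path]:
    """Write the count table, acute-cost table, scenario table and summary.

    Emits ``table2.csv`` (hospitalizations and days by fracture type),
    ``table3.csv`` (acute costs by site × setting with integer percent
    shares), ``table4.csv`` (component × scenario) and ``summary.json``
    (totals, counts, applied overrides). Percent cells are rounded only
    at render time; every rendered total is re-checked against the sum
    of its components.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    t2_cols = [
        "fracture_type", "hospitalizations_women_observed",
        "hospitalizations_men_observed", "hospitalizations_observed",
        "hospitalizations_national", "hospitalized_days_national",
    ]
    t3_cols = [
        "fracture_type", "emergency_care", "acute_admissions", "day_surgery",
        "total_acute_costs", "pct_of_total",
    ]
    t4_cols = ["cost_component"] + list(results)

    base = results.get("base")
    if base is not None:
        sc = base.site_counts
        t2 = pd.DataFrame(
            {
                "fracture_type": sc["site"],
                "hospitalizations_women_observed": sc["hosp_observed_women"].round(1),
                "hospitalizations_men_observed": sc["hosp_observed_men"].round(1),
                "hospitalizations_observed": (
                    sc["hosp_observed_women"] + sc["hosp_observed_men"]
                ).round(1),
                "hospitalizations_national": sc["hosp_national"].round(1),
                "hospitalized_days_national": sc["days_national"].round(1),
            }
        )
        total_row = {"fracture_type": "total"}
        for col in t2_cols[1:]:
            total_row[col] = round(float(t2[col].sum()), 1)
        t2 = pd.concat([t2, pd.DataFrame([total_row])], ignore_index=True)

        am = base.acute_matrix
        grand = float(am["total"].sum())
        t3 = pd.DataFrame(
            {
                "fracture_type": am.index,
                "emergency_care": am["ER"].values,
                "acute_admissions": am["admission"].values,
                "day_surgery": am["day_surgery"].values,
                "total_acute_costs": am["total"].values,
                "pct_of_total": [
                    percent_share(v, grand) for v in am["total"].values
                ],
            }
        )
        check = t3[["emergency_care", "acute_admissions", "day_surgery"]].sum(axis=1)
        if (abs(check - t3["total_acute_costs"]) > 0.01).any():
            raise ConsistencyError("acute table rows do not sum to their totals")
        t3_total = {
            "fracture_type": "total",
            "emergency_care": round(float(t3["emergency_care"].sum()), 2),
            "acute_admissions": round(float(t3["acute_admissions"].sum()), 2),
            "day_surgery": round(float(t3["day_surgery"].sum()), 2),
            "total_acute_costs": round(float(t3["total_acute_costs"].sum()), 2),
            "pct_of_total": 100 if grand else 0,
        }
        t3 = pd.concat([t3, pd.DataFrame([t3_total])], ignore_index=True)
    else:
        t2 = pd.DataFrame(columns=t2_cols)
        t3 = pd.DataFrame(columns=t3_cols)

    rows = []
    for comp in COMPONENTS + ("total",):
        row = {"cost_component": comp}
        for name, res in results.items():
            res.breakdown.check()
            row[name] = getattr(res.breakdown, comp)
        rows.append(row)
    t4 = pd.DataFrame(rows, columns=t4_cols) if results else pd.DataFrame(
        columns=["cost_component"]
    )

    summary = {
        name: {
            "total": res.breakdown.total,
            "components": res.breakdown.as_dict(),
            "counts": res.counts,
            "net_transfers": {
                d: {
                    "discharged_to": nt.discharged_to,
                    "admitted_from": nt.admitted_from,
                    "net": nt.net,
                }
                for d, nt in res.net_transfers.items()
            },
            "overrides_applied": res.overrides_applied,
        }
        for name, res in results.items()
    }

    for fname, frame in (("table2.csv", t2), ("table3.csv", t3), ("table4.csv", t4)):
        path = outdir / fname
        frame.to_csv(path, index=False)
        paths[fname] = path
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=float))
    paths["summary.json"] = spath
    return paths
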