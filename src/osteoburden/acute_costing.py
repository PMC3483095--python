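"""Acute-setting costing: RIW facility costs plus physician fees.

Each encounter is costed patient-level as

    RIW × cost-per-RIW  +  physician visit fees  +  diagnostics  (+ procedure)

The resource intensity weight (RIW) is recorded on the input; the number
of physician assessments per admission follows from the length of stay
with a three-tier fee schedule (admission day; 2nd, 3rd and last day;
every other day). Emergency visits and same-day surgeries are costed
with the same methodology using one admission-day assessment. All
amounts are 2010 Canadian dollars; cells are rounded to the cent only at
aggregation so totals equal sums of cells exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import SITE_CLASSES
from .errors import ConfigurationError, RecordError

SETTINGS = ("admission", "ER", "day_surgery")


def _cents(x: float) -> float:
    return float(np.round(x, 2))


@dataclass
class UnitCostSchedule:
    """Every unit price and rate used by the costing modules (2010 CAD).

    ``diagnostic_cost_by_site`` / ``procedure_cost_by_site`` carry a
    ``"default"`` entry (the published cross-site averages, $75 and
    $1,352) plus optional per-site overrides; the underlying fee
    schedules only publish ranges ($33–$117 and $76–$2,551).
    """

    cost_per_riw_acute: float = 5399.04
    fee_admission_day: float = 79.20
    fee_day2_3_last: float = 55.45
    fee_other_day: float = 29.20
    diagnostic_cost_by_site: dict[str, float] = field(
        default_factory=lambda: {"default": 75.0}
    )
    procedure_cost_by_site: dict[str, float] = field(
        default_factory=lambda: {"default": 1352.0}
    )
    er_procedure_fee: bool = False  # ER visits get no procedure fee by default
    rehab_cost_per_riw_stay: float = 15449.0
    cc_cost_per_riw_day: float = 420.12
    homecare_cost_per_week: float = 168.50
    ltc_cost_per_day: float = 147.77
    gp_consult: float = 56.10
    gp_repeat: float = 42.35
    im_consult: float = 132.50
    im_repeat: float = 82.90
    dispensing_fee: float = 7.00
    hourly_wage: float = 24.12
    hours_per_day: float = 8.0
    cpi_index_by_year: dict[int, float] = field(
        default_factory=lambda: {2007: 111.5, 2008: 114.1, 2009: 114.4, 2010: 116.5}
    )

    def __post_init__(self) -> None:
        monetary = [
            "cost_per_riw_acute", "fee_admission_day", "fee_day2_3_last",
            "fee_other_day", "rehab_cost_per_riw_stay", "cc_cost_per_riw_day",
            "homecare_cost_per_week", "ltc_cost_per_day", "gp_consult",
            "gp_repeat", "im_consult", "im_repeat", "dispensing_fee",
            "hourly_wage", "hours_per_day",
        ]
        for name in monetary:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("diagnostic_cost_by_site", "procedure_cost_by_site"):
            table = getattr(self, name)
            if "default" not in table:
                raise ConfigurationError(f"{name} needs a 'default' entry")
            if any(v <= 0 for v in table.values()):
                raise ConfigurationError(f"{name} values must be > 0")
        if any(v <= 0 for v in self.cpi_index_by_year.values()):
            raise ConfigurationError("CPI indices must be > 0")

    def diagnostic_cost(self, site: str) -> float:
        return self.diagnostic_cost_by_site.get(
            site, self.diagnostic_cost_by_site["default"]
        )

    def procedure_cost(self, site: str) -> float:
        return self.procedure_cost_by_site.get(
            site, self.procedure_cost_by_site["default"]
        )


def physician_fee_for_stay(los_days: int, schedule: UnitCostSchedule) -> float:
    """Physician assessment fees for one admission of ``los_days`` days.

    Day 1 bills the admission fee; days 2, 3 and the final day bill the
    intermediate fee; remaining days bill the subsequent-visit fee. A day
    qualifying both as day 2/3 and as the last day is billed once.
    """
    los_days = int(los_days)
    if los_days < 1:
        raise ValueError(f"length of stay must be >= 1 day, got {los_days}")
    total = schedule.fee_admission_day
    for day in range(2, los_days + 1):
        if day in (2, 3) or day == los_days:
            total += schedule.fee_day2_3_last
        else:
            total += schedule.fee_other_day
    return total


def admission_cost(case, schedule: UnitCostSchedule) -> float:
    """Total facility + fee cost of one acute admission (before attribution).

    ``case`` is a mapping/Series with ``riw``, ``los_days`` and ``site``.
    """
    riw = case["riw"]
    if riw is None or pd.isna(riw) or riw <= 0:
        raise RecordError(
            f"record {case.get('record_id', '?')}: RIW must be positive, got {riw}"
        )
    return (
        riw * schedule.cost_per_riw_acute
        + physician_fee_for_stay(case["los_days"], schedule)
        + schedule.diagnostic_cost(case["site"])
        + schedule.procedure_cost(case["site"])
    )


def ambulatory_cost(case, schedule: UnitCostSchedule) -> float:
    """Cost of one ER visit or same-day surgery (before attribution).

    Same methodology as admissions: RIW cost plus one admission-day
    physician assessment and a diagnostic fee; day surgeries additionally
    attract the procedure fee (ER visits only when ``er_procedure_fee``).
    """
    riw = case["riw"]
    if riw is None or pd.isna(riw) or riw <= 0:
        raise RecordError(
            f"record {case.get('record_id', '?')}: RIW must be positive, got {riw}"
        )
    setting = case["setting"]
    if setting not in ("ER", "day_surgery"):
        raise ConfigurationError(f"unknown ambulatory setting {setting!r}")
    total = (
        riw * schedule.cost_per_riw_acute
        + schedule.fee_admission_day
        + schedule.diagnostic_cost(case["site"])
    )
    if setting == "day_surgery" or schedule.er_procedure_fee:
        total += schedule.procedure_cost(case["site"])
    return total


def case_cost(case, schedule: UnitCostSchedule) -> float:
    """Dispatch to admission or ambulatory costing by the case's setting."""
    if case["setting"] == "admission":
        return admission_cost(case, schedule)
    return ambulatory_cost(case, schedule)


def aggregate_acute(cases: pd.DataFrame, schedule: UnitCostSchedule) -> pd.DataFrame:
    """Attribution-weighted acute costs by site × setting.

    Returns a DataFrame indexed by the six site classes with one column
    per setting plus ``total`` and ``pct_of_total`` columns, and a
    ``total`` row. Cells are rounded to the cent; the totals are sums of
    the rounded cells, so the table is internally additive.
    """
    matrix = pd.DataFrame(
        0.0, index=list(SITE_CLASSES), columns=list(SETTINGS)
    )
    if len(cases):
        costs = cases.apply(lambda row: case_cost(row, schedule), axis=1)
        weighted = costs * cases["attribution_weight"]
        grouped = weighted.groupby([cases["site"], cases["setting"]]).sum()
        for (site, setting), value in grouped.items():
            matrix.loc[site, setting] = _cents(value)
    matrix["total"] = matrix[list(SETTINGS)].sum(axis=1)
    grand = matrix["total"].sum()
    matrix["pct_of_total"] = 0.0 if grand == 0 else 100.0 * matrix["total"] / grand
    totals = matrix[list(SETTINGS) + ["total"]].sum(axis=0)
    totals["pct_of_total"] = 100.0 if grand else 0.0
    matrix.loc["total"] = totals
    return matrix
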