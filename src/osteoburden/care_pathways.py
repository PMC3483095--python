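"""Post-acute care pathways: net transfers and their costs.

Rehabilitation, continuing-care and long-term-care reporting systems do
not carry the reason for admission, so osteoporosis-attributable use of
those facilities is proxied by *net transfers* out of acute care: the
number of people discharged from an acute fracture stay to a destination
minus the number who entered acute care from that same kind of facility
(computed per sex, floored at zero — only the excess counts). Home care
is costed per recipient-week.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .acute_costing import UnitCostSchedule
from .codes import TRANSFER_DESTINATIONS
from .errors import VocabularyError


@dataclass
class NetTransferSummary:
    """Flow accounting for one institutional destination."""

    destination: str
    discharged_to: float
    admitted_from: float
    net: float

    def __post_init__(self) -> None:
        assert self.net <= self.discharged_to + 1e-9


@dataclass
class PostAcuteParams:
    """Durations and per-unit parameters of the post-acute components.

    ``rehab_mean_days`` (days per net rehabilitation transfer) and
    ``homecare_mean_weeks`` are calibrated so published net-transfer and
    recipient counts reproduce the published component costs; neither is
    itself a published value. ``homecare_recipients`` overrides the
    pipeline-derived recipient count when set.
    """

    cc_mean_days: float = 91.0
    cc_mean_riw: float = 1.0
    ltc_mean_days: float = 194.0
    rehab_cost_per_day: float = 736.0
    rehab_mean_days: float = 23.64  # ≈ published total days / net transfers
    rehab_total_days: Optional[float] = None
    rehab_physician_uplift: float = 1.0
    homecare_mean_weeks: float = 28.7993
    homecare_recipients: Optional[float] = None

    def __post_init__(self) -> None:
        positive = [
            "cc_mean_days", "cc_mean_riw", "ltc_mean_days", "rehab_cost_per_day",
            "rehab_mean_days", "rehab_physician_uplift", "homecare_mean_weeks",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def net_transfers(cases: pd.DataFrame, destination: str) -> NetTransferSummary:
    """Attribution-weighted net transfer into one destination.

    Discharges to and admissions from ``destination`` are accumulated per
    sex; each sex's net is floored at zero before summing, so a surplus
    of entrants in one sex cannot offset an excess of discharges in the
    other. Order of records is irrelevant.
    """
    if destination not in TRANSFER_DESTINATIONS:
        raise VocabularyError(
            f"unknown transfer destination {destination!r}; "
            f"expected one of {TRANSFER_DESTINATIONS}"
        )
    discharged_total = admitted_total = net_total = 0.0
    for sex in ("F", "M"):
        sub = cases[cases["sex"] == sex] if len(cases) else cases
        if len(sub):
            w = sub["attribution_weight"]
            discharged = float(w[sub["discharge_destination"] == destination].sum())
            admitted = float(w[sub["admission_source"] == destination].sum())
        else:
            discharged = admitted = 0.0
        discharged_total += discharged
        admitted_total += admitted
        net_total += max(0.0, discharged - admitted)
    return NetTransferSummary(destination, discharged_total, admitted_total, net_total)


def rehab_cost(
    params: PostAcuteParams,
    schedule: UnitCostSchedule,
    *,
    net: Optional[float] = None,
    mean_riw: float = 1.0,
    mode: str = "days",
) -> float:
    """Rehabilitation cost.

    ``days`` mode (primary): total rehabilitation days × cost per day,
    where total days is ``rehab_total_days`` if given, else
    net transfers × ``rehab_mean_days``. ``stay`` mode: net transfers ×
    per-stay RIW cost × mean stay RIW, inflated for physician visits.
    """
    if mode == "days":
        days = params.rehab_total_days
        if days is None:
            if net is None:
                raise ValueError("days mode needs rehab_total_days or a net count")
            days = net * params.rehab_mean_days
        if days < 0:
            raise ValueError("rehabilitation days must be >= 0")
        return days * params.rehab_cost_per_day
    if mode == "stay":
        if net is None:
            raise ValueError("stay mode needs a net transfer count")
        return (
            net * schedule.rehab_cost_per_riw_stay * mean_riw
            * params.rehab_physician_uplift
        )
    raise ValueError(f"unknown rehabilitation costing mode {mode!r}")


def continuing_care_cost(
    net: float, mean_days: float, mean_riw: float, schedule: UnitCostSchedule
) -> float:
    """Continuing-care cost: net transfers × days × RIW × cost/RIW-day."""
    if net < 0:
        raise ValueError("net transfers must be >= 0")
    return net * mean_days * mean_riw * schedule.cc_cost_per_riw_day


def ltc_cost(net: float, mean_days: float, schedule: UnitCostSchedule) -> float:
    """Long-term-care cost: net transfers × days × cost/day."""
    if net < 0:
        raise ValueError("net transfers must be >= 0")
    return net * mean_days * schedule.ltc_cost_per_day


def homecare_cost(
    recipients: float, mean_weeks: float, schedule: UnitCostSchedule
) -> float:
    """Home-care cost: recipients × weeks of service × cost/week."""
    if recipients < 0:
        raise ValueError("recipient count must be >= 0")
    return recipients * mean_weeks * schedule.homecare_cost_per_week
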