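"""Osteoporosis attribution weights for identified fracture cases.

Low-trauma hip and vertebral fractures are attributed to osteoporosis in
full (weight 1.0). For the remaining sites (wrist, humerus, multiple,
other) a sex-specific rate X is solved so that the case-weighted overall
attribution matches an external target — 74.5% in men and 90.4% in women
from cohort estimates of the fraction of low-trauma fractures occurring
at low bone mineral density:

    share_hv * 1.0 + (1 - share_hv) * X = overall_target

where ``share_hv`` is the hip+vertebral share of cases of that sex. A
sensitivity variant replaces the solved rate in women with age-specific
rates (75.7% at 50-59 rising to 91.8% at 80+) from a Quebec fragility
fracture cohort.

Weights are deterministic fractional multipliers carried through counts,
days and costs (expected-value accounting), never Bernoulli draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ConfigurationError


def _default_rocq_rates() -> dict[str, float]:
    # Endpoints are published; intermediate decades interpolate the
    # published rise and are configuration, not estimates.
    return {"50-59": 0.757, "60-69": 0.81, "70-79": 0.87, "80+": 0.918}


@dataclass
class AttributionRates:
    """Attribution parameters.

    ``other_site_rate_by_sex`` may be given directly; when None it is
    solved per sex from ``overall_target_by_sex`` and the observed
    hip+vertebral share. ``rocq_female_rates_by_age_band`` keys are
    ``50-59``, ``60-69``, ``70-79``, ``80+`` (the published table pools
    everyone over 80).
    """

    hip_vertebral_rate: float = 1.0
    overall_target_by_sex: dict[str, float] = field(
        default_factory=lambda: {"M": 0.745, "F": 0.904}
    )
    other_site_rate_by_sex: Optional[dict[str, float]] = None
    rocq_female_rates_by_age_band: dict[str, float] = field(
        default_factory=_default_rocq_rates
    )

    def __post_init__(self) -> None:
        for name, table in [
            ("overall_target_by_sex", self.overall_target_by_sex),
            ("other_site_rate_by_sex", self.other_site_rate_by_sex or {}),
            ("rocq_female_rates_by_age_band", self.rocq_female_rates_by_age_band),
        ]:
            for key, rate in table.items():
                if not 0.0 <= rate <= 1.0:
                    raise ConfigurationError(f"{name}[{key}] = {rate} not in [0, 1]")


def solve_other_site_rate(overall_rate: float, share_hip_vertebral: float) -> float:
    """Solve the non-hip non-vertebral attribution rate X.

    X = (overall − share_hv) / (1 − share_hv), the rate that makes the
    mixture of fully attributed hip/vertebral cases and X-attributed
    other-site cases average to ``overall_rate``.
    """
    if not 0.0 <= overall_rate <= 1.0:
        raise ConfigurationError(f"overall rate {overall_rate} not in [0, 1]")
    if not 0.0 <= share_hip_vertebral < 1.0:
        if share_hip_vertebral == 1.0:
            raise ConfigurationError(
                "hip+vertebral share is 1: other-site rate is undefined"
            )
        raise ConfigurationError(
            f"share_hip_vertebral {share_hip_vertebral} not in [0, 1)"
        )
    x = (overall_rate - share_hip_vertebral) / (1.0 - share_hip_vertebral)
    if not 0.0 <= x <= 1.0:
        raise ConfigurationError(
            f"solved other-site rate {x:.4f} falls outside [0, 1]; the overall "
            f"target {overall_rate} is infeasible at hip+vertebral share "
            f"{share_hip_vertebral}"
        )
    return x


def hip_vertebral_share(cases: pd.DataFrame, sex: str) -> float:
    """Hip+vertebral share of identified cases of one sex (unweighted)."""
    sub = cases[cases["sex"] == sex]
    if len(sub) == 0:
        return 0.0
    return float(sub["site"].isin(["hip", "vertebral"]).mean())


def _rocq_band(age_band: str) -> str:
    return "80+" if age_band in ("80-89", "90+") else age_band


def apply_attribution(
    cases: pd.DataFrame,
    rates: AttributionRates,
    mode: str = "mackey",
) -> pd.DataFrame:
    """Set ``attribution_weight`` on a copy of ``cases``.

    Hip and vertebral cases get exactly 1.0 in every mode. Other sites
    get the sex-specific rate (given, or solved against the observed
    hip+vertebral share of that sex). In ``rocq_women`` mode, women at
    non-hip non-vertebral sites instead get the age-band rate from the
    Quebec cohort table; men are unchanged.
    """
    if mode not in ("mackey", "rocq_women"):
        raise ConfigurationError(f"unknown attribution mode {mode!r}")
    out = cases.copy()
    solved: dict[str, float] = {}
    for sex in ("M", "F"):
        if rates.other_site_rate_by_sex is not None:
            solved[sex] = rates.other_site_rate_by_sex[sex]
        else:
            solved[sex] = solve_other_site_rate(
                rates.overall_target_by_sex[sex], hip_vertebral_share(cases, sex)
            )

    def weight(row) -> float:
        if row["site"] in ("hip", "vertebral"):
            return rates.hip_vertebral_rate
        if mode == "rocq_women" and row["sex"] == "F":
            band = _rocq_band(row["age_band"])
            try:
                return rates.rocq_female_rates_by_age_band[band]
            except KeyError:
                raise ConfigurationError(
                    f"no ROCQ attribution rate configured for age band {band!r}"
                ) from None
        return solved[row["sex"]]

    if len(out):
        out["attribution_weight"] = out.apply(weight, axis=1)
    return out
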