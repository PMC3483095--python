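"""Societal-perspective indirect costs by the human-capital method.

Productivity losses value days not available for work (hospital, post-
acute facility and home-care days) for people of working age, weighted
by the labor-force participation rate of their decade and the average
daily wage. Caregiver wage losses apply a fixed care profile — share of
patients using a caregiver, days of care, share of caregivers employed —
to every osteoporosis-attributable admission. No participation rate is
given above 69, so ages 70+ contribute no productivity loss; caregiver
losses apply to admissions at every age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError


@dataclass
class IndirectParams:
    """Human-capital parameters (wages in 2010 CAD)."""

    participation_rate_by_band: dict[str, float] = field(
        default_factory=lambda: {"50-59": 0.77, "60-69": 0.45}
    )
    hourly_wage: float = 24.12
    hours_per_day: float = 8.0
    caregiver_use_rate: float = 0.472
    caregiver_days: float = 37.0
    caregiver_employment_rate: float = 0.358

    def __post_init__(self) -> None:
        for band, rate in self.participation_rate_by_band.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"participation_rate_by_band[{band}] = {rate} not in [0, 1]"
                )
        for name in ("caregiver_use_rate", "caregiver_employment_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("hourly_wage", "hours_per_day", "caregiver_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def daily_wage(self) -> float:
        return self.hourly_wage * self.hours_per_day


def productivity_loss(days_by_band: dict[str, float], params: IndirectParams) -> float:
    """Wage value of days lost, summed over working-age decade bands.

    ``days_by_band`` maps age-band labels to day counts; only bands with
    a configured participation rate (by default 50-59 and 60-69)
    contribute.
    """
    total = 0.0
    for band, days in days_by_band.items():
        if days < 0:
            raise ValueError(f"negative day count for band {band}")
        rate = params.participation_rate_by_band.get(band)
        if rate is not None:
            total += days * rate * params.daily_wage
    return total


def caregiver_loss(n_admissions: float, params: IndirectParams) -> float:
    """Caregiver wage loss over all osteoporosis-attributable admissions.

    admissions × use rate × days of care × caregiver employment rate ×
    daily wage.
    """
    if n_admissions < 0:
        raise ValueError("admission count must be >= 0")
    return (
        n_admissions
        * params.caregiver_use_rate
        * params.caregiver_days
        * params.caregiver_employment_rate
        * params.daily_wage
    )
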