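"""Synthetic administrative-style record generator.

Real discharge-abstract, ambulatory-care and population data for this kind
of burden-of-illness analysis sit behind restricted data custodians, so
this module fabricates record sets with the same stratified structure:
a fracture-site mix dominated by hip fractures among admissions, a
wrist-dominated day-surgery mix, a roughly 70/30 female/male split, an
age distribution concentrated above 70, right-skewed lengths of stay,
admission-source/discharge-destination flows, and a configurable rate of
severe-trauma contamination so the exclusion filter has work to do.

Everything is driven by one integer seed; per-record-type substreams are
derived from it deterministically, so identical configurations produce
byte-identical CSV files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .codes import ADMISSION_SOURCES, AGE_BANDS, DISCHARGE_DESTINATIONS, SITE_CLASSES
from .errors import ConfigurationError

PROVINCES = ("BC", "AB", "SK", "MB", "ON", "QC", "NB", "NS", "PE", "NL")

# One representative diagnosis code per site class / excluded site; the
# case-identification layer works on prefixes, so a single exemplar per
# prefix family suffices.
_SITE_CODES = {
    "hip": ("S7200", "S7210", "S7220"),
    "vertebral": ("S2200", "S3200"),
    "wrist": ("S5250", "S5260"),
    "humerus": ("S4220", "S4230", "S4240"),
    "multiple": ("T0290",),
    "other": ("S4200", "S8280", "S3230", "S1290"),
}
_EXCLUDED_SITE_CODES = ("S6250", "S0260", "S9200", "S9240")
_NONFRACTURE_CODES = ("J189", "I509", "E119", "N390")
_SEVERE_TRAUMA_CODES = ("V0310", "V4350", "W1300")
_LOW_TRAUMA_CODES = ("W0100", "W1800")
_INTERVENTION_CODES = ("1VA74 fixation", "1VC73 reduction", "1SC80 repair")
_NONFRACTURE_INTERVENTIONS = ("1GZ31 ventilation", "2OT02 assessment")

# Stream ids mixed into the seed so each record type draws independently.
_STREAM_DISCHARGE = 101
_STREAM_ER = 202
_STREAM_DAY_SURGERY = 303
_STREAM_POPULATION = 404


def _default_site_mix() -> dict[str, float]:
    # Admission mix: hip dominates, other/multiple sizeable, wrist modest.
    return {
        "hip": 0.5028,
        "humerus": 0.0450,
        "vertebral": 0.0400,
        "wrist": 0.0846,
        "multiple": 0.1050,
        "other": 0.2226,
    }


def _default_er_site_mix() -> dict[str, float]:
    # ER visits: wrist 30%, hip 23%, other 30%, remainder split.
    return {
        "hip": 0.23,
        "humerus": 0.07,
        "vertebral": 0.05,
        "wrist": 0.30,
        "multiple": 0.05,
        "other": 0.30,
    }


def _default_day_surgery_site_mix() -> dict[str, float]:
    # Day surgeries are overwhelmingly wrist procedures (~80%).
    return {
        "hip": 0.02,
        "humerus": 0.05,
        "vertebral": 0.01,
        "wrist": 0.80,
        "multiple": 0.02,
        "other": 0.10,
    }


def _default_age_band_mix() -> dict[str, float]:
    # >70% of fracture admissions above age 70, peak in the 80s.
    return {"50-59": 0.10, "60-69": 0.18, "70-79": 0.26, "80-89": 0.37, "90+": 0.09}


def _default_province_mix() -> dict[str, float]:
    # Rest-of-Canada mix (no Quebec: acute discharge data exclude it and
    # the pipeline extrapolates Quebec from the other provinces).
    return {
        "BC": 0.175,
        "AB": 0.135,
        "SK": 0.040,
        "MB": 0.045,
        "ON": 0.505,
        "NB": 0.030,
        "NS": 0.040,
        "PE": 0.006,
        "NL": 0.024,
    }


def _default_mean_riw() -> dict[str, float]:
    # Calibrated so per-admission facility+fee costs land near the
    # reported site averages (hip ≈ $20k, wrist ≈ $9k, multiple ≈ $23k).
    return {
        "hip": 3.2,
        "humerus": 2.0,
        "vertebral": 2.0,
        "wrist": 1.3,
        "multiple": 3.9,
        "other": 2.1,
    }


def _default_los_distribution() -> dict[str, dict]:
    # Log-normal rounded up to a whole day; mu/sigma give mean ≈ 14.5 and
    # median ≈ 7 days after the ceiling, matching the skew of acute stays.
    spec = {"name": "lognormal", "mu": math.log(6.6), "sigma": 1.209}
    return {site: dict(spec) for site in SITE_CLASSES}


def _default_destination_probs() -> dict[str, dict[str, float]]:
    hip = {
        "community": 0.27,
        "home_with_homecare": 0.22,
        "rehabilitation": 0.15,
        "continuing_care": 0.06,
        "long_term_care": 0.20,
        "death": 0.08,
        "other": 0.02,
    }
    nonhip = {
        "community": 0.47,
        "home_with_homecare": 0.21,
        "rehabilitation": 0.06,
        "continuing_care": 0.04,
        "long_term_care": 0.12,
        "death": 0.06,
        "other": 0.04,
    }
    return {site: dict(hip if site == "hip" else nonhip) for site in SITE_CLASSES}


def _default_origin_probs() -> dict[str, float]:
    return {
        "community": 0.855,
        "rehabilitation": 0.003,
        "continuing_care": 0.009,
        "long_term_care": 0.125,
        "other": 0.008,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic record generator.

    Probability vectors must sum to 1 (checked to 1e-9). ``p_trauma`` is
    the fraction of records carrying a severe-trauma external-cause code;
    ``p_secondary_only`` the fraction where the fracture appears only as a
    secondary diagnosis alongside a fracture intervention;
    ``p_under50`` / ``p_excluded_site`` / ``p_irrelevant`` inject records
    that the inclusion filters must reject.
    """

    n_records: int = 2000
    seed: int = 0
    site_mix: dict[str, float] = field(default_factory=_default_site_mix)
    er_site_mix: dict[str, float] = field(default_factory=_default_er_site_mix)
    day_surgery_site_mix: dict[str, float] = field(
        default_factory=_default_day_surgery_site_mix
    )
    sex_mix: float = 0.706  # probability female
    age_band_mix: dict[str, float] = field(default_factory=_default_age_band_mix)
    province_mix: dict[str, float] = field(default_factory=_default_province_mix)
    ambulatory_province_mix: dict[str, float] = field(
        default_factory=lambda: {"ON": 1.0}
    )
    mean_riw_by_site: dict[str, float] = field(default_factory=_default_mean_riw)
    riw_shape: float = 9.0  # gamma shape; mean fixed per site
    mean_riw_er: float = 0.20
    mean_riw_day_surgery: float = 0.43
    los_distribution: dict[str, dict] = field(default_factory=_default_los_distribution)
    p_trauma: float = 0.05
    p_secondary_only: float = 0.10
    p_under50: float = 0.03
    p_excluded_site: float = 0.03
    p_irrelevant: float = 0.04
    destination_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_destination_probs
    )
    origin_probs: dict[str, float] = field(default_factory=_default_origin_probs)
    fiscal_year: str = "2007/2008"
    # population table
    population_total: float = 11_000_000.0
    population_province_mix: dict[str, float] = field(
        default_factory=lambda: {
            "BC": 0.135,
            "AB": 0.095,
            "SK": 0.031,
            "MB": 0.034,
            "ON": 0.385,
            "QC": 0.240,
            "NB": 0.024,
            "NS": 0.031,
            "PE": 0.005,
            "NL": 0.020,
        }
    )
    population_female_share: float = 0.53
    population_age_band_mix: dict[str, float] = field(
        default_factory=lambda: {
            "50-59": 0.38,
            "60-69": 0.28,
            "70-79": 0.19,
            "80-89": 0.11,
            "90+": 0.04,
        }
    )

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigurationError("n_records must be >= 0")
        self._check_vector("site_mix", self.site_mix)
        self._check_vector("er_site_mix", self.er_site_mix)
        self._check_vector("day_surgery_site_mix", self.day_surgery_site_mix)
        self._check_vector("age_band_mix", self.age_band_mix)
        self._check_vector("province_mix", self.province_mix)
        self._check_vector("ambulatory_province_mix", self.ambulatory_province_mix)
        self._check_vector("origin_probs", self.origin_probs)
        self._check_vector("population_province_mix", self.population_province_mix)
        self._check_vector("population_age_band_mix", self.population_age_band_mix)
        for site, probs in self.destination_probs.items():
            self._check_vector(f"destination_probs[{site}]", probs)
        for name, p in [
            ("sex_mix", self.sex_mix),
            ("p_trauma", self.p_trauma),
            ("p_secondary_only", self.p_secondary_only),
            ("p_under50", self.p_under50),
            ("p_excluded_site", self.p_excluded_site),
            ("p_irrelevant", self.p_irrelevant),
            ("population_female_share", self.population_female_share),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {p}")
        for site, m in self.mean_riw_by_site.items():
            if m <= 0:
                raise ConfigurationError(f"mean_riw_by_site[{site}] must be > 0")

    @staticmethod
    def _check_vector(name: str, probs: dict[str, float]) -> None:
        if any(p < 0 for p in probs.values()):
            raise ConfigurationError(f"{name} contains a negative probability")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"{name} sums to {total!r}, expected 1")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with fields replaced (re-validates)."""
        return replace(self, **kwargs)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stream)))


def _choice(rng, probs: dict[str, float], size: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=size, p=p / p.sum())]


def _draw_age(rng, band: str) -> int:
    lo, hi = {"50-59": (50, 60), "60-69": (60, 70), "70-79": (70, 80),
              "80-89": (80, 90), "90+": (90, 100)}[band]
    return int(rng.integers(lo, hi))


def _draw_los(rng, spec: dict) -> int:
    name = spec.get("name", "lognormal")
    if name == "lognormal":
        x = math.exp(rng.normal(spec["mu"], spec["sigma"]))
    elif name == "constant":
        x = float(spec["value"])
    else:
        raise ConfigurationError(f"unknown LOS distribution {name!r}")
    return max(1, math.ceil(x))


def _site_code(rng, site: str) -> str:
    codes = _SITE_CODES[site]
    return codes[int(rng.integers(len(codes)))]


def generate_discharge_records(config: GeneratorConfig) -> pd.DataFrame:
    """Generate ``n_records`` synthetic acute-care discharge abstracts.

    Each record carries demographic fields, a most-responsible diagnosis,
    secondary diagnoses, intervention codes, optional severe-trauma
    external-cause codes, a resource intensity weight (RIW), a length of
    stay of at least one day, and admission-source/discharge-destination
    fields. Output is a DataFrame in the ``discharge.csv`` column layout;
    code lists are ``|``-separated strings.
    """
    rng = _rng(config, _STREAM_DISCHARGE)
    n = config.n_records
    rows = []
    sites = _choice(rng, config.site_mix, n)
    sexes = np.where(rng.random(n) < config.sex_mix, "F", "M")
    bands = _choice(rng, config.age_band_mix, n)
    provinces = _choice(rng, config.province_mix, n)
    origins = _choice(rng, config.origin_probs, n)
    for i in range(n):
        site = str(sites[i])
        age = _draw_age(rng, str(bands[i]))
        if rng.random() < config.p_under50:
            age = int(rng.integers(40, 50))
        mean_riw = config.mean_riw_by_site[site]
        riw = float(rng.gamma(config.riw_shape, mean_riw / config.riw_shape))
        riw = max(riw, 0.05)
        los = _draw_los(rng, config.los_distribution[site])
        fracture_code = _site_code(rng, site)
        secondary: list[str] = []
        interventions: list[str] = []
        if rng.random() < config.p_irrelevant:
            mrdx = _NONFRACTURE_CODES[int(rng.integers(len(_NONFRACTURE_CODES)))]
            interventions.append(
                _NONFRACTURE_INTERVENTIONS[int(rng.integers(2))]
            )
        elif rng.random() < config.p_excluded_site:
            mrdx = _EXCLUDED_SITE_CODES[int(rng.integers(len(_EXCLUDED_SITE_CODES)))]
        elif rng.random() < config.p_secondary_only:
            # Fracture visible only as secondary code + fracture intervention.
            mrdx = _NONFRACTURE_CODES[int(rng.integers(len(_NONFRACTURE_CODES)))]
            secondary.append(fracture_code)
            interventions.append(
                _INTERVENTION_CODES[int(rng.integers(len(_INTERVENTION_CODES)))]
            )
        else:
            mrdx = fracture_code
            if rng.random() < 0.6:
                interventions.append(
                    _INTERVENTION_CODES[int(rng.integers(len(_INTERVENTION_CODES)))]
                )
        if rng.random() < config.p_trauma:
            trauma = [_SEVERE_TRAUMA_CODES[int(rng.integers(len(_SEVERE_TRAUMA_CODES)))]]
        else:
            trauma = [_LOW_TRAUMA_CODES[int(rng.integers(len(_LOW_TRAUMA_CODES)))]]
        destination = str(_choice(rng, config.destination_probs[site], 1)[0])
        rows.append(
            {
                "record_id": f"D{i:07d}",
                "age": age,
                "sex": str(sexes[i]),
                "province": str(provinces[i]),
                "fiscal_year": config.fiscal_year,
                "mrdx_code": mrdx,
                "secondary_codes": "|".join(secondary),
                "intervention_codes": "|".join(interventions),
                "trauma_codes": "|".join(trauma),
                "riw": round(riw, 4),
                "los_days": los,
                "admission_source": str(origins[i]),
                "discharge_destination": destination,
            }
        )
    columns = [
        "record_id", "age", "sex", "province", "fiscal_year", "mrdx_code",
        "secondary_codes", "intervention_codes", "trauma_codes", "riw",
        "los_days", "admission_source", "discharge_destination",
    ]
    return pd.DataFrame(rows, columns=columns)


def generate_ambulatory_records(config: GeneratorConfig, setting: str) -> pd.DataFrame:
    """Generate synthetic ER or same-day-surgery records.

    ``setting`` is ``"ER"`` or ``"day_surgery"``. Day-surgery records use
    a wrist-dominated site mix and carry higher RIWs than ER visits.
    Provinces follow ``ambulatory_province_mix`` (by default Ontario only,
    mirroring where complete ambulatory reporting exists).
    """
    if setting == "ER":
        stream, mix, mean_riw = _STREAM_ER, config.er_site_mix, config.mean_riw_er
    elif setting == "day_surgery":
        stream, mix, mean_riw = (
            _STREAM_DAY_SURGERY,
            config.day_surgery_site_mix,
            config.mean_riw_day_surgery,
        )
    else:
        raise ConfigurationError(f"unknown ambulatory setting {setting!r}")
    rng = _rng(config, stream)
    n = config.n_records
    sites = _choice(rng, mix, n)
    sexes = np.where(rng.random(n) < config.sex_mix, "F", "M")
    bands = _choice(rng, config.age_band_mix, n)
    provinces = _choice(rng, config.ambulatory_province_mix, n)
    rows = []
    for i in range(n):
        site = str(sites[i])
        age = _draw_age(rng, str(bands[i]))
        if rng.random() < config.p_under50:
            age = int(rng.integers(40, 50))
        riw = max(float(rng.gamma(config.riw_shape, mean_riw / config.riw_shape)), 0.01)
        if rng.random() < config.p_excluded_site:
            mrdx = _EXCLUDED_SITE_CODES[int(rng.integers(len(_EXCLUDED_SITE_CODES)))]
        else:
            mrdx = _site_code(rng, site)
        if rng.random() < config.p_trauma:
            trauma = [_SEVERE_TRAUMA_CODES[int(rng.integers(len(_SEVERE_TRAUMA_CODES)))]]
        else:
            trauma = [_LOW_TRAUMA_CODES[int(rng.integers(len(_LOW_TRAUMA_CODES)))]]
        rows.append(
            {
                "record_id": f"{'E' if setting == 'ER' else 'S'}{i:07d}",
                "setting": setting,
                "age": age,
                "sex": str(sexes[i]),
                "province": str(provinces[i]),
                "mrdx_code": mrdx,
                "secondary_codes": "",
                "trauma_codes": "|".join(trauma),
                "riw": round(riw, 4),
            }
        )
    columns = [
        "record_id", "setting", "age", "sex", "province", "mrdx_code",
        "secondary_codes", "trauma_codes", "riw",
    ]
    return pd.DataFrame(rows, columns=columns)


def generate_population_table(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic province × sex × age-band population table.

    Cell counts are products of the configured national total and the
    marginal mixes, so the table sums exactly to ``population_total`` and
    scales linearly with it. Counts are reals (population estimates, not
    enumerated heads).
    """
    rows = []
    for prov, p_prov in config.population_province_mix.items():
        for sex, p_sex in (
            ("F", config.population_female_share),
            ("M", 1.0 - config.population_female_share),
        ):
            for band, p_band in config.population_age_band_mix.items():
                rows.append(
                    {
                        "province": prov,
                        "sex": sex,
                        "age_band": band,
                        "count": config.population_total * p_prov * p_sex * p_band,
                    }
                )
    return pd.DataFrame(rows, columns=["province", "sex", "age_band", "count"])
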