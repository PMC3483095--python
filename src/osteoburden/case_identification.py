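"""Fracture case identification from administrative-style records.

Two case definitions are applied to every record aged 50 or over:

1. the most responsible diagnosis (MRDx) is an includable fracture code; or
2. a secondary diagnosis is an includable fracture code *and* an
   intervention indicative of fracture treatment (fixation, immobilization,
   reduction, partial excision, repair) is present.

A record satisfying both is counted once and tagged ``MRDx``. Records
carrying a severe-trauma external-cause code are excluded in the base
case, keeping only low-trauma (fragility) fractures. Site classification
uses all diagnosis codes on the record; two distinct includable sites
yield the ``multiple`` class.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .codes import AGE_BANDS, CodeMap, classify_site

CASE_COLUMNS = [
    "record_id", "setting", "definition", "site", "age", "age_band", "sex",
    "province", "riw", "los_days", "admission_source",
    "discharge_destination", "attribution_weight",
]


def split_codes(value) -> list[str]:
    """Split a ``|``-separated code field into a list of codes."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    s = str(value).strip()
    return [c for c in s.split("|") if c] if s else []


def age_band(age: float) -> Optional[str]:
    """Half-open decade band label for an age, None below 50."""
    if age < 50:
        return None
    if age >= 90:
        return "90+"
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def is_case(record, code_map: CodeMap) -> tuple[bool, Optional[str]]:
    """Apply both case definitions to one record.

    ``record`` is a mapping (or namedtuple/Series) with ``mrdx_code``,
    ``secondary_codes`` and optionally ``intervention_codes`` fields.
    Returns ``(matched, tag)`` where tag is ``"MRDx"`` or
    ``"secondary+intervention"``; the MRDx tag wins when both match.
    """
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    if code_map.is_fracture_code(str(get("mrdx_code", ""))):
        return True, "MRDx"
    secondary = split_codes(get("secondary_codes", ""))
    interventions = split_codes(get("intervention_codes", ""))
    if any(code_map.is_fracture_code(c) for c in secondary) and (
        code_map.has_fracture_intervention(interventions)
    ):
        return True, "secondary+intervention"
    return False, None


def identify_cases(
    records: pd.DataFrame,
    code_map: CodeMap,
    *,
    setting: str = "admission",
    exclude_trauma: bool = True,
    min_age: int = 50,
) -> pd.DataFrame:
    """Filter records down to osteoporosis-relevant fracture cases.

    Keeps records with age >= ``min_age`` that satisfy a case definition
    and (when ``exclude_trauma``) carry no severe-trauma code. Each output
    case has exactly one site class and an ``attribution_weight``
    initialized to 1.0, pending attribution. For ambulatory inputs the
    record's own ``setting`` column overrides the ``setting`` argument.

    Identification is a pure per-record filter: its output is a subset of
    the input and re-applying it to its own output is a no-op.
    """
    if records.empty:
        return pd.DataFrame(columns=CASE_COLUMNS)
    rows = []
    for rec in records.itertuples(index=False):
        if rec.age < min_age:
            continue
        matched, tag = is_case(rec, code_map)
        if not matched:
            continue
        trauma = split_codes(getattr(rec, "trauma_codes", ""))
        if exclude_trauma and code_map.is_severe_trauma(trauma):
            continue
        diagnosis_codes = [str(rec.mrdx_code)] + split_codes(
            getattr(rec, "secondary_codes", "")
        )
        site = classify_site(diagnosis_codes, code_map)
        if site is None:
            continue
        rows.append(
            {
                "record_id": rec.record_id,
                "setting": getattr(rec, "setting", setting),
                "definition": tag,
                "site": site,
                "age": rec.age,
                "age_band": age_band(rec.age),
                "sex": rec.sex,
                "province": rec.province,
                "riw": float(rec.riw),
                "los_days": int(getattr(rec, "los_days", 0)) or None,
                "admission_source": getattr(rec, "admission_source", None),
                "discharge_destination": getattr(rec, "discharge_destination", None),
                "attribution_weight": 1.0,
            }
        )
    return pd.DataFrame(rows, columns=CASE_COLUMNS)
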