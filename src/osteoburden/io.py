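"""CSV / YAML input-output.

Record tables travel as UTF-8 CSV with a header row, one record per row,
code lists as ``|``-separated strings. Configuration (generator, code
map, unit costs) travels as YAML mapping onto the corresponding
dataclasses; unknown keys are configuration errors so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .acute_costing import UnitCostSchedule
from .attribution import AttributionRates
from .care_pathways import PostAcuteParams
from .codes import CodeMap, default_code_map
from .errors import ConfigurationError
from .indirect_costs import IndirectParams
from .synthetic_data import GeneratorConfig

_STRING_COLS = ["secondary_codes", "intervention_codes", "trauma_codes"]


def read_records(path) -> pd.DataFrame:
    """Read a discharge or ambulatory CSV, keeping code lists as strings."""
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLS} | {
        "record_id": "string", "sex": "string", "province": "string",
    })
    for col in _STRING_COLS:
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _from_mapping(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown {name} keys: {sorted(unknown)}")
    return cls(**data)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def load_generator_config(path) -> GeneratorConfig:
    return _from_mapping(GeneratorConfig, load_yaml(path), "generator config")


def load_schedule(path) -> UnitCostSchedule:
    data = load_yaml(path)
    if "cpi_index_by_year" in data:
        data["cpi_index_by_year"] = {
            int(k): float(v) for k, v in data["cpi_index_by_year"].items()
        }
    return _from_mapping(UnitCostSchedule, data, "unit cost schedule")


def load_attribution_rates(path) -> AttributionRates:
    return _from_mapping(AttributionRates, load_yaml(path), "attribution rates")


def load_postacute_params(path) -> PostAcuteParams:
    return _from_mapping(PostAcuteParams, load_yaml(path), "post-acute params")


def load_indirect_params(path) -> IndirectParams:
    return _from_mapping(IndirectParams, load_yaml(path), "indirect params")


def load_code_map(path=None) -> CodeMap:
    """Load a CodeMap from YAML; None returns the documented defaults."""
    if path is None:
        return default_code_map()
    data = load_yaml(path)
    kwargs = {}
    if "site_prefixes" in data:
        kwargs["site_prefixes"] = {
            site: tuple(prefixes) for site, prefixes in data["site_prefixes"].items()
        }
    for key in (
        "excluded_site_prefixes",
        "severe_trauma_prefixes",
        "fracture_intervention_keywords",
    ):
        if key in data:
            kwargs[key] = tuple(data[key])
    unknown = set(data) - {
        "site_prefixes", "excluded_site_prefixes", "severe_trauma_prefixes",
        "fracture_intervention_keywords",
    }
    if unknown:
        raise ConfigurationError(f"unknown code map keys: {sorted(unknown)}")
    return CodeMap(**kwargs)
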