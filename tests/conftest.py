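import pandas as pd
import pytest

from osteoburden.acute_costing import UnitCostSchedule
from osteoburden.codes import default_code_map
from osteoburden.synthetic_data import (
    GeneratorConfig,
    generate_ambulatory_records,
    generate_discharge_records,
    generate_population_table,
)


@pytest.fixture(scope="session")
def code_map():
    return default_code_map()


@pytest.fixture(scope="session")
def schedule():
    return UnitCostSchedule()


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_records=600, seed=20)


@pytest.fixture(scope="session")
def discharge(small_config):
    return generate_discharge_records(small_config)


@pytest.fixture(scope="session")
def ambulatory(small_config):
    return pd.concat(
        [
            generate_ambulatory_records(small_config, "ER"),
            generate_ambulatory_records(small_config, "day_surgery"),
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def population(small_config):
    return generate_population_table(small_config)


def make_case(
    site="hip",
    sex="F",
    age=80,
    setting="admission",
    riw=1.0,
    los_days=5,
    weight=1.0,
    province="ON",
    admission_source="community",
    discharge_destination="community",
    record_id="X0000001",
):
    """One fracture-case row in the identified-cases layout."""
    band = "90+" if age >= 90 else f"{(age // 10) * 10}-{(age // 10) * 10 + 9}"
    return {
        "record_id": record_id,
        "setting": setting,
        "definition": "MRDx",
        "site": site,
        "age": age,
        "age_band": band,
        "sex": sex,
        "province": province,
        "riw": riw,
        "los_days": los_days,
        "admission_source": admission_source,
        "discharge_destination": discharge_destination,
        "attribution_weight": weight,
    }


def case_frame(rows):
    return pd.DataFrame(rows)
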