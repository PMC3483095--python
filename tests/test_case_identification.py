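"""Case definitions, site classification, and filter behaviour."""

import pandas as pd
import pytest

from osteoburden.case_identification import identify_cases, is_case, split_codes
from osteoburden.codes import CodeMap, classify_site
from osteoburden.errors import ConfigurationError


def record(
    mrdx="S7200", secondary="", interventions="", trauma="", age=80,
    record_id="R1", sex="F", province="ON", riw=1.5, los=5,
):
    return {
        "record_id": record_id,
        "age": age,
        "sex": sex,
        "province": province,
        "fiscal_year": "2007/2008",
        "mrdx_code": mrdx,
        "secondary_codes": secondary,
        "intervention_codes": interventions,
        "trauma_codes": trauma,
        "riw": riw,
        "los_days": los,
        "admission_source": "community",
        "discharge_destination": "community",
    }


class TestClassifySite:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            (["S7200"], "hip"),
            (["S5250"], "wrist"),
            (["S2200"], "vertebral"),
            (["S4230"], "humerus"),
            (["T0290"], "multiple"),  # explicit multiple-fracture code
            (["S7200", "S5250"], "multiple"),  # two distinct sites
            (["S7200", "S7210"], "hip"),  # two codes, one site
            (["S6250"], None),  # finger: not osteoporosis-related
            (["S0260"], None),  # face/skull
            (["S3210"], None),  # sacrum
            (["J189"], None),  # not a fracture at all
            ([], None),
        ],
    )
    def test_examples(self, codes, expected, code_map):
        assert classify_site(codes, code_map) == expected

    def test_pairwise_two_site_rule_matches_enumeration(self, code_map):
        # cross-check the >=2-distinct-sites rule against explicit enumeration
        exemplars = {
            "hip": "S7200", "vertebral": "S2200", "wrist": "S5250",
            "humerus": "S4220", "other": "S8280",
        }
        for a, ca in exemplars.items():
            for b, cb in exemplars.items():
                got = classify_site([ca, cb], code_map)
                assert got == (a if a == b else "multiple")

    def test_excluded_plus_included_keeps_included_site(self, code_map):
        assert classify_site(["S6250", "S7200"], code_map) == "hip"

    def test_conflicting_prefixes_rejected(self):
        with pytest.raises(ConfigurationError):
            CodeMap(site_prefixes={"hip": ("S72",), "wrist": ("S72",)})
        with pytest.raises(ConfigurationError):
            CodeMap(
                site_prefixes={"hip": ("S72",)},
                excluded_site_prefixes=("S72",),
            )


class TestIsCase:
    def test_mrdx_fracture_matches_definition_one(self, code_map):
        matched, tag = is_case(record(mrdx="S7200"), code_map)
        assert matched and tag == "MRDx"

    def test_secondary_plus_intervention_matches_definition_two(self, code_map):
        rec = record(mrdx="J189", secondary="S5250", interventions="1VA74 fixation")
        matched, tag = is_case(rec, code_map)
        assert matched and tag == "secondary+intervention"

    def test_secondary_without_intervention_is_not_a_case(self, code_map):
        rec = record(mrdx="J189", secondary="S5250")
        assert is_case(rec, code_map) == (False, None)

    def test_both_definitions_tagged_mrdx(self, code_map):
        rec = record(mrdx="S7200", secondary="S5250", interventions="1VA74 fixation")
        assert is_case(rec, code_map)[1] == "MRDx"

    def test_excluded_site_secondary_does_not_fire(self, code_map):
        rec = record(mrdx="J189", secondary="S6250", interventions="1VA74 fixation")
        assert is_case(rec, code_map) == (False, None)


class TestIdentifyCases:
    def test_under_50_excluded_even_with_hip_mrdx(self, code_map):
        records = pd.DataFrame([record(age=49), record(age=50, record_id="R2")])
        cases = identify_cases(records, code_map)
        assert list(cases["record_id"]) == ["R2"]

    def test_severe_trauma_excluded_in_base_case_only(self, code_map):
        records = pd.DataFrame([record(trauma="V0310")])
        assert len(identify_cases(records, code_map)) == 0
        assert len(identify_cases(records, code_map, exclude_trauma=False)) == 1

    def test_low_trauma_code_not_excluded(self, code_map):
        records = pd.DataFrame([record(trauma="W0100")])  # fall at same level
        assert len(identify_cases(records, code_map)) == 1

    def test_matches_per_record_oracle_on_synthetic_records(
        self, discharge, code_map
    ):
        cases = identify_cases(discharge, code_map)
        expected_ids = []
        for _, rec in discharge.iterrows():
            if rec["age"] < 50:
                continue
            codes = [rec["mrdx_code"]] + split_codes(rec["secondary_codes"])
            mrdx_hit = code_map.is_fracture_code(rec["mrdx_code"])
            sec_hit = any(
                code_map.is_fracture_code(c)
                for c in split_codes(rec["secondary_codes"])
            ) and code_map.has_fracture_intervention(
                split_codes(rec["intervention_codes"])
            )
            if not (mrdx_hit or sec_hit):
                continue
            if code_map.is_severe_trauma(split_codes(rec["trauma_codes"])):
                continue
            expected_ids.append(rec["record_id"])
        assert list(cases["record_id"]) == expected_ids

    def test_output_is_subset_and_reapplication_is_stable(self, discharge, code_map):
        cases = identify_cases(discharge, code_map)
        assert set(cases["record_id"]) <= set(discharge["record_id"])
        matched = discharge[discharge["record_id"].isin(cases["record_id"])]
        again = identify_cases(matched, code_map)
        pd.testing.assert_frame_equal(
            cases.reset_index(drop=True), again.reset_index(drop=True)
        )

    def test_every_case_has_exactly_one_site_class(self, discharge, code_map):
        cases = identify_cases(discharge, code_map)
        assert cases["site"].isin(
            ["hip", "vertebral", "wrist", "humerus", "multiple", "other"]
        ).all()
        assert cases["site"].notna().all()

    def test_initial_attribution_weight_is_one(self, discharge, code_map):
        cases = identify_cases(discharge, code_map)
        assert (cases["attribution_weight"] == 1.0).all()

    def test_empty_input_gives_empty_cases(self, code_map):
        cases = identify_cases(pd.DataFrame(), code_map)
        assert len(cases) == 0
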