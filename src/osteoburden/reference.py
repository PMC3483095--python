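"""Published FY 2007/2008 Canadian burden-of-osteoporosis estimates.

These are the national figures published for fiscal year 2007/2008
(expressed in 2010 Canadian dollars) by the burden-of-illness study this
package's methodology follows. They are *inputs and benchmarks*, not
outputs: the underlying administrative records are access-restricted, so
the published tables serve as report targets, as defaults for
pipeline-level quantities that enter as observed inputs (physician
visits, drug spend), and as fixtures for arithmetic-consistency checks.
"""

from __future__ import annotations

# --- Hospitalization counts by fracture type (national) ----------------
HOSPITALIZATIONS_BY_SITE = {
    "hip": 28_867,
    "humerus": 2_585,
    "vertebral": 2_297,
    "wrist": 4_858,
    "multiple": 6_028,
    "other": 12_778,
}
HOSPITALIZED_DAYS_BY_SITE = {
    "hip": 448_776,
    "humerus": 30_141,
    "vertebral": 34_490,
    "wrist": 24_132,
    "multiple": 124_000,
    "other": 171_055,
}
ADMISSIONS_NATIONAL = 57_413
ADMISSIONS_REST_OF_CANADA = 44_707  # observed outside Quebec
ADMISSIONS_QUEBEC_ESTIMATED = 12_706  # age–sex extrapolated
HOSPITALIZED_DAYS_NATIONAL = 832_594
ER_VISITS_NATIONAL = 112_740
DAY_SURGERIES_NATIONAL = 3_433

# --- Acute-care costs by fracture type and setting (2010 CAD) ----------
ACUTE_COSTS = {
    #            ER           admissions    day surgery
    "hip": (40_493_177, 582_058_662, 288_169),
    "humerus": (11_681_974, 32_324_504, 451_514),
    "vertebral": (5_186_182, 31_720_622, 237_393),
    "wrist": (55_420_934, 43_028_096, 9_497_406),
    "multiple": (9_322_424, 141_035_749, 321_292),
    "other": (38_803_610, 178_163_216, 1_239_783),
}
ACUTE_ROW_TOTALS = {
    "hip": 622_840_008,
    "humerus": 44_457_992,
    "vertebral": 37_144_197,
    "wrist": 107_946_436,
    "multiple": 150_679_465,
    "other": 218_206_609,
}
ACUTE_ADMISSION_COLUMN_TOTAL = 1_008_330_849
ACUTE_GRAND_TOTAL = 1_181_274_707

# --- Post-acute flow counts --------------------------------------------
REHAB_DISCHARGED_TO = 5_714
REHAB_ADMITTED_FROM = 133
REHAB_NET_TRANSFERS = 5_581
REHAB_TOTAL_DAYS = 131_944
CONTINUING_CARE_NET_TRANSFERS = 2_391
LTC_DISCHARGED_TO = 8_707
LTC_ADMITTED_FROM = 7_152
HOMECARE_RECIPIENTS = 50_398

# --- Physician and drug inputs -----------------------------------------
PHYSICIAN_VISITS = 2_363_293  # consistent with the published $143M at 81% GP
PHYSICIAN_SHARE_GP = 0.81
DRUG_SPEND_PUBLIC = 278_000_000.0
DRUG_SPEND_PRIVATE_OBSERVED = 73_355_648.0  # at 65% capture
PRIVATE_CLAIM_COVERAGE = 0.65

# --- Indirect-cost inputs ----------------------------------------------
WORK_DAYS_LOST_50_69 = 3_123_298

# --- Base-case and scenario cost components (2010 CAD) ------------------
BASE_CASE_COMPONENTS = {
    "acute": 1_181_274_707,
    "rehabilitation": 97_169_606,
    "continuing_care": 112_720_625,
    "long_term_care": 28_275_046,
    "home_care": 244_565_735,
    "physician": 142_589_880,
    "drugs": 390_854_843,
    "indirect": 115_311_966,
}
BASE_CASE_TOTAL = 2_312_762_408

OP_ONLY_COMPONENTS = {
    "acute": 1_219_450_008,
    "rehabilitation": 103_457_541,
    "continuing_care": 119_837_738,
    "long_term_care": 28_275_046,
    "home_care": 244_565_735,
    "physician": 142_589_880,
    "drugs": 390_854_843,
    "indirect": 115_311_966,
}
OP_ONLY_TOTAL = 2_364_342_757

LTC_PREVALENCE_COMPONENT = 1_641_017_974
LTC_PREVALENCE_RESIDENTS = 30_425
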