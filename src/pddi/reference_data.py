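"""Published aggregate results of the 2018 Polish national analgesic pDDI
screen of National Health Fund dispensation data.

The claim-level national data are access-restricted, but the published
aggregates — per-rule histograms of months-with-pDDI per case, patient-month
totals, and same-prescriber percentages — are mutually consistent and fully
determine the statistics layer's outputs.  They serve two roles here: as the
calibration for the synthetic generator's defaults, and as the input to
:func:`pddi.synthetic_data.expand_reference_fixture`, which inverts them into
claim-level records so the whole pipeline can be exercised end to end.
"""
from __future__ import annotations

YEAR = 2018

#: National population used as the prevalence denominator.
POPULATION = 38_413_139

#: Canonical presentation order of the nine screened rules.
RULE_ORDER = [
    "nsaid_antihypertensive",
    "nsaid_nsaid",
    "nsaid_gc",
    "nsaid_ssri_snri",
    "nsaid_oac",
    "nsaid_antiplatelet",
    "opioid_gabapentinoid",
    "opioid_benzodiazepine",
    "tramadol_ssri_snri",
]

#: Per rule: number of cases by count of calendar months with the pDDI
#: present (index 0 = 1 month ... index 11 = all 12 months).
MONTH_HISTOGRAM: dict[str, list[int]] = {
    "nsaid_antihypertensive": [992914, 290676, 126927, 69148, 41074, 26243,
                               13719, 8361, 5784, 4047, 2888, 1794],
    "nsaid_nsaid": [462379, 51461, 13501, 5246, 2639, 1449,
                    790, 474, 312, 186, 118, 85],
    "nsaid_gc": [164826, 25039, 10222, 5515, 3292, 2029,
                 1078, 623, 386, 248, 149, 97],
    "nsaid_ssri_snri": [45951, 9739, 3346, 1637, 893, 486,
                        244, 135, 95, 72, 50, 18],
    "nsaid_oac": [34048, 7775, 2799, 1201, 459, 191, 63, 30, 6, 4, 4, 2],
    "nsaid_antiplatelet": [15972, 3542, 1418, 740, 381, 253,
                           135, 88, 42, 30, 16, 12],
    "opioid_gabapentinoid": [9470, 3067, 1553, 1061, 653, 481,
                             327, 205, 147, 91, 51, 12],
    "opioid_benzodiazepine": [481, 47, 18, 14, 9, 4, 6, 3, 0, 1, 2, 1],
    "tramadol_ssri_snri": [297, 78, 39, 15, 16, 13, 8, 5, 8, 2, 3, 3],
}

#: Per rule: % of cases attributed to a single prescriber, total
#: patient-months, and % of patient-months attributed to a single prescriber.
ATTRIBUTION: dict[str, dict[str, float]] = {
    "nsaid_antihypertensive": {"pct_cases": 78.3, "patient_months": 2903210,
                               "pct_patient_months": 80.2},
    "nsaid_nsaid": {"pct_cases": 75.4, "patient_months": 664985,
                    "pct_patient_months": 76.2},
    "nsaid_gc": {"pct_cases": 77.1, "patient_months": 317551,
                 "pct_patient_months": 79.6},
    "nsaid_ssri_snri": {"pct_cases": 45.3, "patient_months": 94525,
                        "pct_patient_months": 49.0},
    "nsaid_oac": {"pct_cases": 73.1, "patient_months": 67083,
                  "pct_patient_months": 75.5},
    "nsaid_antiplatelet": {"pct_cases": 71.3, "patient_months": 36340,
                           "pct_patient_months": 74.2},
    "opioid_gabapentinoid": {"pct_cases": 87.3, "patient_months": 37525,
                             "pct_patient_months": 85.7},
    "opioid_benzodiazepine": {"pct_cases": 71.3, "patient_months": 864,
                              "pct_patient_months": 74.4},
    "tramadol_ssri_snri": {"pct_cases": 60.2, "patient_months": 1045,
                           "pct_patient_months": 64.7},
}

TOTAL_CASES = sum(sum(v) for v in MONTH_HISTOGRAM.values())          # 2485787
TOTAL_PATIENT_MONTHS = sum(int(v["patient_months"])
                           for v in ATTRIBUTION.values())            # 4123128
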