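"""Flag potential drug-drug interactions in a tiny hand-built claims stream.

The screening rule: a pDDI is present in a patient-month when two drugs on
opposite sides of an interaction rule are dispensed within the same
calendar month.  Each flag records the smallest day gap between qualifying
fills and whether any qualifying pair came from one prescriber.
"""
from datetime import date

from pddi import (DispensationRecord, StudyWindow, build_cases, flag_months,
                  load_ruleset)

claims = [
    # same month, same prescriber -> co-prescribed NSAID+antihypertensive
    DispensationRecord("anna", date(2018, 3, 2), drug_name="ibuprofen",
                       prescriber_id="D01"),
    DispensationRecord("anna", date(2018, 3, 20), drug_name="ramipril",
                       prescriber_id="D01"),
    # …and the same pair again in June, this time from two prescribers
    DispensationRecord("anna", date(2018, 6, 5), drug_name="ibuprofen",
                       prescriber_id="D01"),
    DispensationRecord("anna", date(2018, 6, 6), drug_name="ramipril",
                       prescriber_id="D02"),
    # adjacent months never pair: no flag for bartek
    DispensationRecord("bartek", date(2018, 3, 31), drug_name="naproxen",
                       prescriber_id="D03"),
    DispensationRecord("bartek", date(2018, 4, 1), drug_name="losartan",
                       prescriber_id="D03"),
    # tramadol only counts at >= 200 mg daily dose: no flag for celina
    DispensationRecord("celina", date(2018, 5, 5), drug_name="tramadol",
                       prescriber_id="D04", daily_dose_mg=100),
    DispensationRecord("celina", date(2018, 5, 9), drug_name="paroxetine",
                       prescriber_id="D04"),
]

rs = load_ruleset("default")
window = StudyWindow.year(2018)

flags = flag_months(claims, rs, window)
print("month flags:")
for f in flags:
    print(f"  {f.patient_id}: {f.rule_id} in {f.month.year}-"
          f"{f.month.month:02d}, gap {f.min_interval_days} d, "
          f"co-prescribed={f.co_prescribed}")

print("\ncases (one per patient and rule):")
for c in build_cases(flags):
    print(f"  {c.patient_id}: {c.rule_id}, {c.n_months} month(s), "
          f"co-prescribed case={c.case_co_prescribed}")

# Expected: anna has one nsaid_antihypertensive case spanning 2 months, a
# co-prescribed case under the default "any month" policy; bartek and
# celina produce no flags (month boundary / sub-threshold dose).
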