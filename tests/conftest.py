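import datetime as dt

import numpy as np
import pytest

from pddi import DispensationRecord, StudyWindow, load_ruleset


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset("default")


@pytest.fixture(scope="session")
def window():
    return StudyWindow.year(2018)


def random_claims(rng: np.random.Generator, n_patients: int = 200,
                  n_records: int = 2000) -> list[DispensationRecord]:
    """A messy toy claims stream: study drugs, out-of-study drugs, random
    doses (some tramadol above and below the threshold), empty prescribers,
    dates spilling outside the study year."""
    drugs = ["ibuprofen", "diclofenac", "ketoprofen", "ramipril", "losartan",
             "metoprolol", "prednisone", "warfarin", "clopidogrel",
             "paroxetine", "venlafaxine", "tramadol", "morphine", "fentanyl",
             "gabapentin", "pregabalin", "diazepam", "alprazolam",
             "omeprazole", "metformin", "simvastatin"]
    out = []
    start = dt.date(2017, 11, 1)
    for _ in range(n_records):
        drug = drugs[rng.integers(0, len(drugs))]
        dose = None
        if drug == "tramadol":
            dose = float(rng.choice([50, 100, 200, 300]))
        elif rng.random() < 0.2:
            dose = float(rng.integers(1, 50) * 10)
        prescriber = "" if rng.random() < 0.15 \
            else f"D{rng.integers(0, 12):02d}"
        out.append(DispensationRecord(
            patient_id=f"p{rng.integers(0, n_patients):03d}",
            dispense_date=start + dt.timedelta(
                days=int(rng.integers(0, 430))),
            drug_name=drug, prescriber_id=prescriber, daily_dose_mg=dose))
    return out
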