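import datetime as dt

import numpy as np
import pandas as pd
import pytest
from _oracle import brute_force_flags

from pddi.claims_io import DispensationRecord, MonthKey
from pddi.detector import (DetectorError, MonthFlag, build_cases,
                           build_cases_frame, flag_months, flag_months_frame)

D = dt.date


def rec(pid, date, drug, rx="", dose=None):
    return DispensationRecord(pid, date, drug_name=drug, prescriber_id=rx,
                              daily_dose_mg=dose)


class TestMonthRule:
    def test_same_month_pair_is_flagged(self, ruleset, window):
        flags = flag_months([rec("p", D(2018, 3, 2), "ibuprofen", "A"),
                             rec("p", D(2018, 3, 20), "ramipril", "A")],
                            ruleset, window)
        assert flags == [MonthFlag("p", "nsaid_antihypertensive",
                                   MonthKey(2018, 3), co_prescribed=True,
                                   min_interval_days=18, n_pairs=1)]

    def test_adjacent_months_never_flag(self, ruleset, window):
        flags = flag_months([rec("p", D(2018, 3, 31), "ibuprofen", "A"),
                             rec("p", D(2018, 4, 1), "ramipril", "A")],
                            ruleset, window)
        assert flags == []

    @pytest.mark.parametrize("dose, n_expected", [
        (None, 0), (100.0, 0), (199.0, 0), (200.0, 1), (400.0, 1)])
    def test_tramadol_dose_threshold(self, ruleset, window, dose, n_expected):
        """Only high-dose tramadol months qualify against SSRIs/SNRIs."""
        flags = flag_months([rec("p", D(2018, 5, 5), "tramadol", "A", dose),
                             rec("p", D(2018, 5, 6), "paroxetine", "B")],
                            ruleset, window)
        assert len(flags) == n_expected

    def test_same_substance_never_self_pairs(self, ruleset, window):
        flags = flag_months([rec("p", D(2018, 6, 1), "ketoprofen", "A"),
                             rec("p", D(2018, 6, 15), "ketoprofen", "B")],
                            ruleset, window)
        assert flags == []

    def test_two_distinct_nsaids_pair(self, ruleset, window):
        flags = flag_months([rec("p", D(2018, 6, 1), "ketoprofen", "A"),
                             rec("p", D(2018, 6, 1), "naproxen", "B")],
                            ruleset, window)
        assert [f.rule_id for f in flags] == ["nsaid_nsaid"]
        assert flags[0].min_interval_days == 0
        assert not flags[0].co_prescribed

    def test_unknown_prescriber_never_co_prescribes(self, ruleset, window):
        flags = flag_months([rec("p", D(2018, 6, 1), "ibuprofen", ""),
                             rec("p", D(2018, 6, 9), "ramipril", "")],
                            ruleset, window)
        assert len(flags) == 1 and not flags[0].co_prescribed

    def test_min_interval_over_qualifying_pairs_only(self, ruleset, window):
        # the low-dose tramadol fill sits closer to the SSRI but cannot
        # qualify, so the interval comes from the high-dose fill
        flags = flag_months(
            [rec("p", D(2018, 5, 10), "tramadol", "A", 100.0),
             rec("p", D(2018, 5, 2), "tramadol", "A", 200.0),
             rec("p", D(2018, 5, 11), "paroxetine", "B")],
            ruleset, window)
        assert len(flags) == 1
        assert flags[0].min_interval_days == 9

    def test_out_of_window_records_ignored(self, ruleset, window):
        flags = flag_months([rec("p", D(2017, 12, 2), "ibuprofen", "A"),
                             rec("p", D(2017, 12, 20), "ramipril", "A")],
                            ruleset, window)
        assert flags == []

    def test_empty_input(self, ruleset, window):
        assert flag_months([], ruleset, window) == []
        assert build_cases([]) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_toy_dataset_matches_brute_force(self, ruleset, window,
                                                    seed):
        """Vectorised detection is pair-for-pair identical to quadratic
        all-pairs enumeration on a messy random claims stream."""
        from conftest import random_claims
        records = random_claims(np.random.default_rng(seed),
                                n_patients=200, n_records=2000)
        expected = brute_force_flags(records, ruleset, window)
        got = {(f.patient_id, f.rule_id, f.month.year, f.month.month):
               (f.n_pairs, f.min_interval_days, f.co_prescribed)
               for f in flag_months(records, ruleset, window)}
        assert got == expected

    def test_order_independence(self, ruleset, window):
        rng = np.random.default_rng(7)
        from conftest import random_claims
        records = random_claims(rng, n_patients=50, n_records=400)
        base = flag_months_frame(records, ruleset, window)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        pd.testing.assert_frame_equal(
            base, flag_months_frame(shuffled, ruleset, window))

    def test_monotonicity_under_added_records(self, ruleset, window):
        """Adding a dispensation never removes a flag and never flips
        co-prescribed from true to false."""
        rng = np.random.default_rng(11)
        from conftest import random_claims
        records = random_claims(rng, n_patients=20, n_records=120)
        extras = random_claims(rng, n_patients=20, n_records=30)

        def as_map(recs):
            return {(f.patient_id, f.rule_id, f.month): f
                    for f in flag_months(recs, ruleset, window)}

        current = records
        before = as_map(current)
        for extra in extras:
            current = current + [extra]
            after = as_map(current)
            for key, f in before.items():
                assert key in after
                assert after[key].co_prescribed or not f.co_prescribed
            before = after


class TestCases:
    def _flags(self):
        return [
            MonthFlag("P", "r", MonthKey(2018, 1), False, 5, 1),
            MonthFlag("P", "r", MonthKey(2018, 6), True, 0, 2),
            MonthFlag("Q", "r", MonthKey(2018, 2), False, 3, 1),
        ]

    def test_aggregation_any_policy(self):
        cases = build_cases(self._flags())
        p = next(c for c in cases if c.patient_id == "P")
        assert p.n_months == 2
        assert p.months == (MonthKey(2018, 1), MonthKey(2018, 6))
        assert p.case_co_prescribed           # "any" month co-prescribed
        assert p.patient_months_co_prescribed == 1
        q = next(c for c in cases if c.patient_id == "Q")
        assert q.n_months == 1 and not q.case_co_prescribed

    @pytest.mark.parametrize("policy, expected", [
        ("any", True), ("all", False), ("majority", False)])
    def test_attribution_policies(self, policy, expected):
        cases = build_cases(self._flags(), policy=policy)
        p = next(c for c in cases if c.patient_id == "P")
        assert p.case_co_prescribed is expected

    def test_unknown_policy(self):
        with pytest.raises(DetectorError, match="policy"):
            build_cases(self._flags(), policy="some")

    def test_duplicate_month_flag_is_hard_error(self):
        flags = self._flags() + [MonthFlag("P", "r", MonthKey(2018, 1),
                                           True, 2, 1)]
        with pytest.raises(DetectorError, match="duplicate"):
            build_cases(flags)

    def test_patient_month_conservation(self, ruleset, window):
        """Per rule, Σ n_months over cases equals the number of month
        flags — the identity behind the patient-month column."""
        from conftest import random_claims
        records = random_claims(np.random.default_rng(3))
        flags = flag_months_frame(records, ruleset, window)
        cases = build_cases_frame(flags)
        per_rule_flags = flags.groupby("rule_id").size()
        per_rule_case_months = cases.groupby("rule_id")["n_months"].sum()
        assert per_rule_case_months.sort_index().equals(
            per_rule_flags.sort_index())
        co_flags = flags.groupby("rule_id")["co_prescribed"].sum()
        co_case_months = cases.groupby("rule_id")[
            "patient_months_co_prescribed"].sum()
        assert co_case_months.sort_index().astype(int).equals(
            co_flags.sort_index().astype(int))
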