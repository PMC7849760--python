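import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pddi import reference_data as ref
from pddi.claims_io import StudyWindow
from pddi.detector import build_cases_frame, flag_months_frame
from pddi.stats import persistence_summary, persistence_table
from pddi.synthetic_data import (PlantedRuleSpec, SimConfig, SimConfigError,
                                 expand_reference_fixture, simulate,
                                 simulate_to_files)


def small_config(seed=0, **kw):
    window = StudyWindow.year(2018)
    dist = [0.5, 0.3, 0.1, 0.1] + [0.0] * 8
    planted = {"nsaid_gc": PlantedRuleSpec(100, dist, 0.7)}
    defaults = dict(seed=seed, n_patients=300, window=window,
                    planted=planted, background_rate=0.1,
                    near_miss_rate=0.05, sub_threshold_tramadol_rate=0.05)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulate:
    def test_determinism_byte_identical(self, tmp_path):
        a = simulate_to_files(small_config(seed=42), tmp_path / "a")
        b = simulate_to_files(small_config(seed=42), tmp_path / "b")
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()
        c = simulate_to_files(small_config(seed=43), tmp_path / "c")
        assert a[0].read_bytes() != c[0].read_bytes()

    def test_planted_cases_recovered_exactly(self, ruleset, window):
        """With clean background, the detector recovers each planted episode
        with its exact month set and co-prescribed months."""
        cfg = small_config(seed=1, background_rate=0.0, near_miss_rate=0.0,
                           sub_threshold_tramadol_rate=0.0)
        res = simulate(cfg)
        flags = flag_months_frame(res.claims, ruleset, window)
        cases = build_cases_frame(flags)
        assert len(cases) == 100
        assert set(cases["rule_id"]) == {"nsaid_gc"}
        truth = res.truth.set_index("patient_id")
        got = cases.set_index("patient_id")
        assert got["n_months"].to_dict() == truth["n_months"].to_dict()
        # month sets and co-months match the sidecar exactly
        flag_months_by_pid = {
            pid: set(zip(g["year"], g["month"]))
            for pid, g in flags.groupby("patient_id")}
        for pid, row in truth.iterrows():
            planted = {(int(m[:4]), int(m[5:7]))
                       for m in row["months"].split("|")}
            assert flag_months_by_pid[pid] == planted
            co = set() if not row["co_months"] else {
                (int(m[:4]), int(m[5:7]))
                for m in row["co_months"].split("|")}
            got_co = {
                (y, m) for y, m, c in zip(
                    *(flags.loc[flags["patient_id"] == pid, k]
                      for k in ("year", "month", "co_prescribed"))) if c}
            assert got_co == co

    def test_co_prescribed_fraction_within_binomial_bounds(self, ruleset,
                                                           window):
        p = 0.7
        cfg = small_config(seed=2, background_rate=0.0, near_miss_rate=0.0,
                           sub_threshold_tramadol_rate=0.0)
        res = simulate(cfg)
        flags = flag_months_frame(res.claims, ruleset, window)
        n = len(flags)
        k = int(flags["co_prescribed"].sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], n, p)
        assert lo <= k <= hi

    def test_near_misses_only_yield_nothing(self, ruleset, window):
        cfg = small_config(near_miss_rate=1.0, background_rate=0.0,
                           sub_threshold_tramadol_rate=0.0)
        cfg.planted = {}
        res = simulate(cfg)
        assert len(res.claims) > 0
        assert flag_months_frame(res.claims, ruleset, window).empty

    def test_background_only_no_false_positives(self, ruleset, window):
        cfg = small_config(seed=9, near_miss_rate=0.0, background_rate=0.6,
                           sub_threshold_tramadol_rate=0.0)
        cfg.planted = {}
        res = simulate(cfg)
        assert len(res.claims) > 0
        assert flag_months_frame(res.claims, ruleset, window).empty

    def test_sub_threshold_tramadol_only_no_flags(self, ruleset, window):
        cfg = small_config(near_miss_rate=0.0, background_rate=0.0,
                           sub_threshold_tramadol_rate=1.0)
        cfg.planted = {}
        res = simulate(cfg)
        assert (res.claims["daily_dose_mg"].dropna() < 200).all()
        assert flag_months_frame(res.claims, ruleset, window).empty

    def test_infeasible_config_rejected_before_output(self):
        with pytest.raises(SimConfigError, match="exceed"):
            simulate(small_config(n_patients=50))
        with pytest.raises(SimConfigError, match="sum"):
            cfg = small_config()
            cfg.planted["nsaid_gc"].month_count_distribution = [0.5] * 12
            simulate(cfg)
        with pytest.raises(SimConfigError, match="not in rule set"):
            cfg = small_config()
            cfg.planted["bogus"] = PlantedRuleSpec(
                1, [1.0] + [0.0] * 11, 0.5)
            simulate(cfg)

    def test_default_config_is_valid_and_study_shaped(self, ruleset):
        cfg = SimConfig.default(seed=0)
        cfg.validate(ruleset)
        assert set(cfg.planted) == set(ref.RULE_ORDER)
        # volumes proportional to the national screen at 1/1000
        assert cfg.planted["nsaid_antihypertensive"].n_cases == 1584
        assert cfg.planted["tramadol_ssri_snri"].n_cases == 1

    def test_config_yaml_roundtrip(self, tmp_path):
        import yaml
        cfg = small_config(seed=5)
        doc = {
            "seed": cfg.seed, "n_patients": cfg.n_patients,
            "window": {"year": 2018},
            "background_rate": cfg.background_rate,
            "near_miss_rate": cfg.near_miss_rate,
            "sub_threshold_tramadol_rate": cfg.sub_threshold_tramadol_rate,
            "planted": {
                rid: {"n_cases": s.n_cases,
                      "month_count_distribution":
                          list(s.month_count_distribution),
                      "p_co_prescribed_month": s.p_co_prescribed_month}
                for rid, s in cfg.planted.items()},
        }
        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(doc))
        again = SimConfig.from_yaml(p)
        assert again == cfg


class TestFixtureExpansion:
    def test_zero_counts_empty_claims(self):
        res = expand_reference_fixture(
            counts={"nsaid_gc": [0] * 12}, attribution={}, scale=1.0)
        assert res.claims.empty
        assert res.total_cases == 0

    def test_scaled_expansion_recovers_scaled_aggregates(self, ruleset):
        """Pipeline on a 1/1000 expansion reproduces the scaled histogram
        and same-prescriber counts exactly; large-rule persistence means
        stay within 0.05 of the full-scale means."""
        res = expand_reference_fixture(scale=1 / 1000, seed=3)
        flags = flag_months_frame(res.claims, ruleset, res.window)
        cases = build_cases_frame(flags)
        table = persistence_table(cases, res.window,
                                  rule_order=ref.RULE_ORDER)
        for rid, expected in res.histogram.items():
            assert table.counts.loc[rid].tolist() == expected, rid
        from pddi.stats import attribution_summary
        attr = attribution_summary(cases)
        for rid in ref.RULE_ORDER:
            assert attr.per_rule.loc[rid, "n_cases_same_prescriber"] \
                == res.co_cases[rid]
            assert attr.per_rule.loc[rid, "n_patient_months_same_prescriber"] \
                == res.co_patient_months[rid]
        s = persistence_summary(table)
        m = np.arange(1, 13)
        for rid, hist in ref.MONTH_HISTOGRAM.items():
            if s.loc[rid, "n"] >= 200:
                full_mean = (m * np.array(hist)).sum() / sum(hist)
                assert abs(s.loc[rid, "mean_months"] - full_mean) < 0.05

    def test_requested_attribution_realised_to_integer_rounding(self):
        """Realised same-prescriber fractions reproduce the requested
        percentages at 1-decimal display precision."""
        res = expand_reference_fixture(scale=1 / 100, seed=0)
        for rid, c in res.histogram.items():
            n = sum(c)
            pm = int((np.arange(1, 13) * np.array(c)).sum())
            want_cases = round(
                n * ref.ATTRIBUTION[rid]["pct_cases"] / 100)
            want_months = round(
                pm * ref.ATTRIBUTION[rid]["pct_patient_months"] / 100)
            assert res.co_cases[rid] == want_cases, rid
            assert res.co_patient_months[rid] == want_months, rid
        assert res.notes == []

    def test_unreachable_percentage_clamped_and_reported(self):
        # 2 single-month cases cannot host 90% of cases AND only 50% of
        # months: co months are clamped to the co case count
        res = expand_reference_fixture(
            counts={"nsaid_gc": [2] + [0] * 11},
            attribution={"nsaid_gc": {"pct_cases": 100.0,
                                      "pct_patient_months": 50.0}},
            scale=1.0)
        assert res.co_cases["nsaid_gc"] == 2
        assert res.co_patient_months["nsaid_gc"] == 2
        assert res.notes and "nsaid_gc" in res.notes[0]

    def test_determinism(self):
        a = expand_reference_fixture(scale=1 / 500, seed=8)
        b = expand_reference_fixture(scale=1 / 500, seed=8)
        pd.testing.assert_frame_equal(a.claims, b.claims)
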