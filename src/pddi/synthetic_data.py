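"""Synthetic dispensation data with known ground truth.

Two generators are provided:

* :func:`simulate` — a constructive simulator: interaction episodes are
  written directly into the claims stream (one drug from each side of the
  rule in each chosen month), together with non-interacting background
  fills, "near-miss" pairs split across adjacent months, and sub-threshold
  tramadol months.  Because generation is constructive rather than
  behavioural, the planted cases and their month counts are recovered
  *exactly* by the detector, which is what makes the generator usable as a
  test oracle.  A ground-truth sidecar records what was planted.

* :func:`expand_reference_fixture` — inverts the published national
  aggregate tables (per-rule month-count histograms and same-prescriber
  percentages) into claim-level records, optionally scaled down, so that
  running the full pipeline on the expansion reproduces the published
  statistics.

Patients are partitioned by role (one rule's planted cases, near-miss,
sub-threshold tramadol, or single-substance background), so no synthetic
patient can trigger a rule other than the one planted for them.
"""
from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import reference_data as ref
from .claims_io import CLAIM_COLUMNS, Dialect, StudyWindow, write_claims
from .rulebook import InteractionRule, RuleSet, load_ruleset

TRUTH_COLUMNS = ["patient_id", "rule_id", "n_months", "months", "co_months"]


class SimConfigError(ValueError):
    """The requested simulation is infeasible."""


@dataclass
class PlantedRuleSpec:
    """How many cases to plant for one rule, with what persistence shape."""
    n_cases: int
    #: probability of each month-count 1..window length (sums to 1)
    month_count_distribution: Sequence[float]
    #: probability that a planted interaction month is co-prescribed
    p_co_prescribed_month: float


@dataclass
class SimConfig:
    seed: int
    n_patients: int
    window: StudyWindow
    planted: dict[str, PlantedRuleSpec]
    #: per patient-month probability of a background (non-conflicting) fill
    background_rate: float = 0.05
    #: per background-pool patient probability of being a "near miss":
    #: a conflicting pair split across two adjacent months
    near_miss_rate: float = 0.02
    #: per background-pool patient probability of a sub-threshold tramadol
    #: month (tramadol below the dose condition + an SSRI/SNRI)
    sub_threshold_tramadol_rate: float = 0.01

    def validate(self, ruleset: RuleSet) -> None:
        known = set(ruleset.rule_ids)
        total_planted = 0
        for rule_id, spec in self.planted.items():
            if rule_id not in known:
                raise SimConfigError(f"planted rule {rule_id!r} not in rule set")
            if spec.n_cases < 0:
                raise SimConfigError(f"{rule_id}: n_cases must be >= 0")
            if spec.n_cases > self.n_patients:
                raise SimConfigError(
                    f"{rule_id}: {spec.n_cases} planted cases exceed "
                    f"{self.n_patients} patients")
            dist = np.asarray(spec.month_count_distribution, dtype=float)
            if len(dist) != self.window.n_months or dist.min() < 0 \
                    or abs(dist.sum() - 1.0) > 1e-9:
                raise SimConfigError(
                    f"{rule_id}: month_count_distribution must have "
                    f"{self.window.n_months} non-negative entries summing to 1")
            if not 0.0 <= spec.p_co_prescribed_month <= 1.0:
                raise SimConfigError(
                    f"{rule_id}: p_co_prescribed_month outside [0, 1]")
            total_planted += spec.n_cases
        if total_planted > self.n_patients:
            raise SimConfigError(
                f"{total_planted} planted cases exceed {self.n_patients} "
                "patients (each planted case needs its own patient)")
        for name in ("background_rate", "near_miss_rate",
                     "sub_threshold_tramadol_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} outside [0, 1]")

    @classmethod
    def default(cls, seed: int = 0, scale: float = 1 / 1000) -> "SimConfig":
        """Defaults calibrated to the published national screen: per-rule
        case volumes, month-count distributions and co-prescribing rates are
        the published aggregates scaled down (1/1000 by default)."""
        window = StudyWindow.year(ref.YEAR)
        planted = {}
        total = 0
        for rule_id in ref.RULE_ORDER:
            hist = np.asarray(ref.MONTH_HISTOGRAM[rule_id], dtype=float)
            n = max(1, int(round(hist.sum() * scale)))
            planted[rule_id] = PlantedRuleSpec(
                n_cases=n,
                month_count_distribution=(hist / hist.sum()).tolist(),
                p_co_prescribed_month=(
                    ref.ATTRIBUTION[rule_id]["pct_patient_months"] / 100.0),
            )
            total += n
        return cls(seed=seed, n_patients=2 * total, window=window,
                   planted=planted)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        from .claims_io import MonthKey
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        window = doc.get("window", {})
        if "year" in window:
            sw = StudyWindow.year(int(window["year"]))
        else:
            sw = StudyWindow(MonthKey(*window["start"]),
                             MonthKey(*window["end"]))
        planted = {
            rid: PlantedRuleSpec(
                n_cases=int(s["n_cases"]),
                month_count_distribution=s["month_count_distribution"],
                p_co_prescribed_month=float(s["p_co_prescribed_month"]))
            for rid, s in (doc.get("planted") or {}).items()}
        return cls(seed=int(doc.get("seed", 0)),
                   n_patients=int(doc["n_patients"]), window=sw,
                   planted=planted,
                   background_rate=float(doc.get("background_rate", 0.05)),
                   near_miss_rate=float(doc.get("near_miss_rate", 0.02)),
                   sub_threshold_tramadol_rate=float(
                       doc.get("sub_threshold_tramadol_rate", 0.01)))


@dataclass
class SimResult:
    claims: pd.DataFrame
    truth: pd.DataFrame  # one row per planted (patient, rule) episode


def _days_in(window: StudyWindow) -> np.ndarray:
    return np.array([calendar.monthrange(i // 12, i % 12 + 1)[1]
                     for i in range(window.start.index,
                                    window.end.index + 1)])


def _month_starts(window: StudyWindow) -> np.ndarray:
    """datetime64[M] for each month index of the window."""
    return (np.arange(window.start.index, window.end.index + 1)
            - 1970 * 12).astype("datetime64[M]")


def _rosters(ruleset: RuleSet) -> dict[str, np.ndarray]:
    out: dict[str, list[str]] = {}
    for e in ruleset.catalog:
        out.setdefault(e.class_label, []).append(e.code or e.name)
    return {k: np.array(sorted(v)) for k, v in out.items()}


def _side_roster(rule_side, rosters) -> np.ndarray:
    return np.concatenate([rosters[lbl] for lbl in sorted(rule_side.labels)])


def simulate(config: SimConfig,
             ruleset: Optional[RuleSet] = None) -> SimResult:
    """Generate a claims table plus a ground-truth sidecar (seeded)."""
    ruleset = ruleset or load_ruleset("default")
    config.validate(ruleset)
    rng = np.random.default_rng(config.seed)
    rosters = _rosters(ruleset)
    window = config.window
    W = window.n_months
    days_in = _days_in(window)
    month_starts = _month_starts(window)
    rules_by_id = {r.rule_id: r for r in ruleset.rules}

    claims_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    next_pid = 0

    def month_str(local_m: int) -> str:
        mk = window.start.index + local_m
        return f"{mk // 12:04d}-{mk % 12 + 1:02d}"

    def episode_records(pid: str, rule: InteractionRule, months: np.ndarray,
                        co_flags: np.ndarray) -> None:
        ros_a = _side_roster(rule.side_a, rosters)
        ros_b = _side_roster(rule.side_b, rosters)
        for local_m, co in zip(months, co_flags):
            a = rng.choice(ros_a)
            b = rng.choice(ros_b)
            if rule.require_distinct_substance:
                while b == a:
                    b = rng.choice(ros_b)
            rx_a = f"D{rng.integers(0, 100_000):05d}"
            rx_b = rx_a if co else f"D{(int(rx_a[1:]) + 1 + rng.integers(0, 99_998)) % 100_000:05d}"
            date_a = month_starts[local_m] + np.timedelta64(
                int(rng.integers(0, days_in[local_m])), "D")
            date_b = month_starts[local_m] + np.timedelta64(
                int(rng.integers(0, days_in[local_m])), "D")
            dose_a = rule.min_daily_dose_mg if rule.min_daily_dose_mg else None
            claims_rows.append((pid, pd.Timestamp(date_a), a, "", rx_a, dose_a))
            claims_rows.append((pid, pd.Timestamp(date_b), b, "", rx_b, None))

    # planted interaction episodes, one dedicated patient per case
    for rule_id in sorted(config.planted):
        spec = config.planted[rule_id]
        rule = rules_by_id[rule_id]
        dist = np.asarray(spec.month_count_distribution, dtype=float)
        for _ in range(spec.n_cases):
            pid = f"P{next_pid:07d}"
            next_pid += 1
            n_months = int(rng.choice(np.arange(1, W + 1), p=dist))
            months = np.sort(rng.choice(W, size=n_months, replace=False))
            co = rng.random(n_months) < spec.p_co_prescribed_month
            episode_records(pid, rule, months, co)
            truth_rows.append((
                pid, rule_id, n_months,
                "|".join(month_str(m) for m in months),
                "|".join(month_str(m) for m, c in zip(months, co) if c)))

    # the remaining pool: near-miss / sub-threshold tramadol / background
    tram_rule = rules_by_id.get("tramadol_ssri_snri")
    all_rules = [rules_by_id[r] for r in sorted(rules_by_id)]
    all_substances = np.sort(np.unique(np.concatenate(
        [v for v in rosters.values()])))
    for _ in range(config.n_patients - next_pid):
        pid = f"P{next_pid:07d}"
        next_pid += 1
        u = rng.random()
        if u < config.near_miss_rate and W >= 2:
            # conflicting pair split across adjacent months: never a flag
            rule = all_rules[int(rng.integers(0, len(all_rules)))]
            m0 = int(rng.integers(0, W - 1))
            ros_a = _side_roster(rule.side_a, rosters)
            ros_b = _side_roster(rule.side_b, rosters)
            a, b = rng.choice(ros_a), rng.choice(ros_b)
            if rule.require_distinct_substance:
                while b == a:
                    b = rng.choice(ros_b)
            dose = rule.min_daily_dose_mg if rule.min_daily_dose_mg else None
            for m, drug, ds in ((m0, a, dose), (m0 + 1, b, None)):
                date = month_starts[m] + np.timedelta64(
                    int(rng.integers(0, days_in[m])), "D")
                claims_rows.append((pid, pd.Timestamp(date), drug, "",
                                    f"D{rng.integers(0, 100_000):05d}", ds))
        elif u < config.near_miss_rate + config.sub_threshold_tramadol_rate \
                and tram_rule is not None:
            # tramadol below the dose threshold + SSRI/SNRI, same month
            m = int(rng.integers(0, W))
            ros_b = _side_roster(tram_rule.side_b, rosters)
            low_dose = tram_rule.min_daily_dose_mg / 2 \
                if tram_rule.min_daily_dose_mg else 50.0
            for drug, ds in ((_side_roster(tram_rule.side_a, rosters)[0],
                              low_dose), (rng.choice(ros_b), None)):
                date = month_starts[m] + np.timedelta64(
                    int(rng.integers(0, days_in[m])), "D")
                claims_rows.append((pid, pd.Timestamp(date), drug, "",
                                    f"D{rng.integers(0, 100_000):05d}", ds))
        else:
            # background: one substance per patient -> can never pair
            drug = rng.choice(all_substances)
            fills = np.flatnonzero(rng.random(W) < config.background_rate)
            for m in fills:
                date = month_starts[m] + np.timedelta64(
                    int(rng.integers(0, days_in[m])), "D")
                claims_rows.append((pid, pd.Timestamp(date), drug, "",
                                    f"D{rng.integers(0, 100_000):05d}", None))

    claims = pd.DataFrame(claims_rows, columns=CLAIM_COLUMNS)
    claims["daily_dose_mg"] = pd.to_numeric(claims["daily_dose_mg"])
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimResult(claims=claims, truth=truth)


def simulate_to_files(config: SimConfig, out_dir: Union[str, Path],
                      ruleset: Optional[RuleSet] = None,
                      dialect: Optional[Dialect] = None
                      ) -> tuple[Path, Path]:
    """Run :func:`simulate` and write ``claims.csv`` + ``ground_truth.csv``.

    Deterministic: the same config (seed included) yields byte-identical
    files."""
    res = simulate(config, ruleset)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    claims_path = out_dir / "claims.csv"
    truth_path = out_dir / "ground_truth.csv"
    write_claims(res.claims, claims_path, dialect)
    res.truth.to_csv(truth_path, index=False)
    return claims_path, truth_path


@dataclass
class FixtureResult:
    """Claim-level expansion of aggregate tables, plus what was realised."""
    claims: pd.DataFrame
    histogram: dict[str, list[int]]      # realised per-rule month-count histogram
    co_cases: dict[str, int]             # realised same-prescriber cases
    co_patient_months: dict[str, int]    # realised same-prescriber months
    window: StudyWindow
    notes: list[str] = field(default_factory=list)

    @property
    def total_cases(self) -> int:
        return sum(sum(v) for v in self.histogram.values())


def _scale_histogram(counts: Sequence[int], scale: float) -> np.ndarray:
    """Scale a histogram preserving the rounded total and the shape
    (largest-remainder apportionment); a non-empty rule keeps >= 1 case."""
    c = np.asarray(counts, dtype=float)
    total = int(round(c.sum() * scale))
    if c.sum() > 0:
        total = max(total, 1)
    if total == 0:
        return np.zeros(len(c), dtype=int)
    raw = c * scale * (total / max(c.sum() * scale, 1e-300))
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _allocate_co(counts: np.ndarray, k_cases: int, k_months: int
                 ) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Choose, per month-count bin, how many cases are same-prescriber and
    how many of their months are, hitting the requested totals as closely as
    integers allow.

    Cases with the longest persistence are made co-prescribed first, which
    maximises the number of co-prescribed months reachable for a fixed
    number of co-prescribed cases.  Returns (co_cases_per_bin,
    co_month_budget_per_bin, realised_cases, realised_months).
    """
    W = len(counts)
    k_cases = int(np.clip(k_cases, 0, counts.sum()))
    co_cases = np.zeros(W, dtype=int)
    remaining = k_cases
    for m in range(W - 1, -1, -1):
        take = min(remaining, counts[m])
        co_cases[m] = take
        remaining -= take
    capacity = int((co_cases * np.arange(1, W + 1)).sum())
    k_months = int(np.clip(k_months, min(k_cases, capacity), capacity))
    co_months = co_cases.copy()  # every co case has >= 1 co month
    extra = k_months - int(co_cases.sum())
    for m in range(W - 1, 0, -1):
        if extra <= 0:
            break
        room = co_cases[m] * m  # each case in bin m can absorb m-1 extras
        take = min(extra, room)
        co_months[m] += take
        extra -= take
    return co_cases, co_months, k_cases, int(co_months.sum())


def expand_reference_fixture(
        counts: Optional[Mapping[str, Sequence[int]]] = None,
        attribution: Optional[Mapping[str, Mapping[str, float]]] = None,
        window: Optional[StudyWindow] = None,
        scale: float = 1.0,
        seed: int = 0,
        ruleset: Optional[RuleSet] = None) -> FixtureResult:
    """Expand aggregate per-rule tables into claim-level records.

    For each rule and month-count ``m``, emits ``counts[rule][m-1]``
    synthetic patients, each with one qualifying drug pair in exactly ``m``
    distinct calendar months; prescriber IDs are assigned so the realised
    case-level and month-level same-prescriber fractions match the requested
    percentages to the nearest achievable integer counts (deviations are
    reported in ``notes``).  Defaults to the published national aggregates;
    ``scale`` shrinks the expansion for fast runs.

    Fully vectorised: the unscaled national expansion (~2.5 M cases, ~8.2 M
    records) builds in well under two minutes.
    """
    ruleset = ruleset or load_ruleset("default")
    counts = counts if counts is not None else ref.MONTH_HISTOGRAM
    attribution = attribution if attribution is not None else ref.ATTRIBUTION
    window = window or StudyWindow.year(ref.YEAR)
    W = window.n_months
    rng = np.random.default_rng(seed)
    rules_by_id = {r.rule_id: r for r in ruleset.rules}
    rosters = _rosters(ruleset)
    days_in = _days_in(window)
    month_starts = _month_starts(window)

    # Records are accumulated as integer codes and materialised once at the
    # end as categorical columns, so the full national expansion never builds
    # per-row Python strings.
    catalog_codes = np.sort(np.unique(np.concatenate(
        [v for v in _rosters(ruleset).values()])))
    RX_POOL = 100_000
    pid_parts: list[np.ndarray] = []
    date_parts: list[np.ndarray] = []
    drug_parts: list[np.ndarray] = []
    rx_parts: list[np.ndarray] = []
    dose_parts: list[np.ndarray] = []
    patient_label_parts: list[np.ndarray] = []
    pid_offset = 0

    out_hist: dict[str, list[int]] = {}
    out_co_cases: dict[str, int] = {}
    out_co_months: dict[str, int] = {}
    notes: list[str] = []

    for rule_id, raw_counts in counts.items():
        rule = rules_by_id[rule_id]
        if len(raw_counts) != W:
            raise ValueError(f"{rule_id}: histogram needs {W} bins")
        if min(raw_counts) < 0:
            raise ValueError(f"{rule_id}: negative count")
        c = _scale_histogram(raw_counts, scale)
        n = int(c.sum())
        out_hist[rule_id] = c.tolist()
        if n == 0:
            out_co_cases[rule_id] = 0
            out_co_months[rule_id] = 0
            continue
        pm = int((c * np.arange(1, W + 1)).sum())
        att = attribution.get(rule_id, {})
        k_cases = int(round(n * att.get("pct_cases", 0.0) / 100.0))
        k_months = int(round(pm * att.get("pct_patient_months", 0.0) / 100.0))
        co_cases_bin, co_months_bin, got_c, got_m = \
            _allocate_co(c, k_cases, k_months)
        if (got_c, got_m) != (k_cases, k_months):
            notes.append(
                f"{rule_id}: requested {k_cases} co cases / {k_months} co "
                f"months, nearest achievable {got_c} / {got_m}")
        out_co_cases[rule_id] = got_c
        out_co_months[rule_id] = got_m

        # per-case arrays, bin by bin (cases in one bin share month-count m)
        pid_base = 0
        ros_a = _side_roster(rule.side_a, rosters)
        ros_b = _side_roster(rule.side_b, rosters)
        gidx_a = np.searchsorted(catalog_codes, ros_a)
        gidx_b = np.searchsorted(catalog_codes, ros_b)
        dose_a = rule.min_daily_dose_mg  # None for all but the tramadol rule
        for m_idx in range(W):
            k = int(c[m_idx])
            if k == 0:
                continue
            m = m_idx + 1
            # distinct months per case: first m of a random permutation
            months = np.argsort(rng.random((k, W)), axis=1)[:, :m]
            # co-month allocation inside the bin: the first `n_co` cases are
            # co-prescribed; extras fill cases up to m months, front first
            n_co = int(co_cases_bin[m_idx])
            extra = int(co_months_bin[m_idx]) - n_co
            co_per_case = np.zeros(k, dtype=int)
            co_per_case[:n_co] = 1
            if extra > 0 and m > 1:
                full, part = divmod(extra, m - 1)
                co_per_case[:full] += m - 1
                if full < n_co:
                    co_per_case[full] += part
            # flatten case-months
            case_idx = np.repeat(np.arange(k), m)
            month_local = months.ravel()
            rank = np.tile(np.arange(m), k)
            is_co = rank < np.repeat(co_per_case, m)

            n_rows = k * m
            rx_a = rng.integers(0, RX_POOL, size=n_rows)
            rx_off = rng.integers(1, RX_POOL, size=n_rows)
            rx_b = np.where(is_co, rx_a, (rx_a + rx_off) % RX_POOL)
            day_a = (rng.random(n_rows)
                     * days_in[month_local]).astype(int)
            day_b = (rng.random(n_rows)
                     * days_in[month_local]).astype(int)
            sub_a = rng.integers(0, len(ros_a), size=n_rows)
            sub_b = rng.integers(0, len(ros_b), size=n_rows)
            if rule.require_distinct_substance:
                clash = ros_a[sub_a] == ros_b[sub_b]
                sub_b = np.where(
                    clash, (sub_b + 1 + rng.integers(0, len(ros_b) - 1,
                                                     size=n_rows))
                    % len(ros_b), sub_b)
            dates_a = month_starts[month_local] \
                + day_a.astype("timedelta64[D]")
            dates_b = month_starts[month_local] \
                + day_b.astype("timedelta64[D]")
            pid_code = (pid_offset + pid_base + case_idx).astype("int64")
            pid_base += k

            pid_parts.append(np.concatenate([pid_code, pid_code]))
            date_parts.append(np.concatenate([dates_a, dates_b]))
            drug_parts.append(np.concatenate([gidx_a[sub_a], gidx_b[sub_b]])
                              .astype("int16"))
            rx_parts.append(np.concatenate([rx_a, rx_b]).astype("int32"))
            dose_col = np.full(2 * n_rows, np.nan)
            if dose_a is not None:
                dose_col[:n_rows] = dose_a
            dose_parts.append(dose_col)
        patient_label_parts.append(
            np.char.add(f"{rule_id}-", np.arange(n).astype("U8")))
        pid_offset += n

    if pid_parts:
        patient_categories = np.concatenate(patient_label_parts)
        claims = pd.DataFrame({
            "patient_id": pd.Categorical.from_codes(
                np.concatenate(pid_parts), categories=patient_categories),
            "dispense_date": np.concatenate(date_parts)
            .astype("datetime64[ns]"),
            "drug_code": pd.Categorical.from_codes(
                np.concatenate(drug_parts), categories=catalog_codes),
            "drug_name": "",
            "prescriber_id": pd.Categorical.from_codes(
                np.concatenate(rx_parts),
                categories=np.char.add("D", np.arange(RX_POOL).astype("U6"))),
            "daily_dose_mg": np.concatenate(dose_parts),
        })[CLAIM_COLUMNS]
    else:
        claims = pd.DataFrame(columns=CLAIM_COLUMNS)
    return FixtureResult(claims=claims, histogram=out_hist,
                         co_cases=out_co_cases,
                         co_patient_months=out_co_months,
                         window=window, notes=notes)
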