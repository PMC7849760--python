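"""The screening algorithm: same-calendar-month co-dispensation detection.

A potential drug-drug interaction (pDDI) is flagged for a patient-month when
two dispensations whose classes sit on opposite sides of an interaction rule
fall in the same calendar month (subject to the rule's dose and
distinct-substance conditions).  Month flags are then aggregated into cases:
one case per (patient, rule) with at least one flagged month in the study
window.  Each flag records the smallest day gap among its qualifying pairs
and whether any qualifying pair came from a single prescriber
(co-prescribing); an empty prescriber ID is "unknown" and never matches.

The implementation is vectorised over pandas frames; ``flag_months`` /
``build_cases`` also accept and return plain record objects for small
inputs.  For rules whose two sides select identical classes, qualifying
pairs are counted once per unordered distinct-substance pair; for the
packaged rules the sides are otherwise disjoint, so every qualifying pair is
counted exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .claims_io import (CLAIM_COLUMNS, DispensationRecord, MonthKey,
                        StudyWindow, records_to_frame)
from .rulebook import RuleSet

#: Case-level attribution policies: a case is "same prescriber" if ANY / ALL
#: / a MAJORITY of its flagged months were co-prescribed.
ATTRIBUTION_POLICIES = ("any", "all", "majority")

FLAG_COLUMNS = ["patient_id", "rule_id", "year", "month", "n_pairs",
                "min_interval_days", "co_prescribed"]
CASE_COLUMNS = ["patient_id", "rule_id", "n_months", "case_co_prescribed",
                "patient_months_co_prescribed"]


@dataclass(frozen=True)
class MonthFlag:
    """One flagged patient-month for one rule."""
    patient_id: str
    rule_id: str
    month: MonthKey
    co_prescribed: bool
    min_interval_days: int
    n_pairs: int


@dataclass(frozen=True)
class CaseRecord:
    """One (patient, rule) pDDI case over the study window."""
    patient_id: str
    rule_id: str
    months: tuple[MonthKey, ...]
    case_co_prescribed: bool
    patient_months_co_prescribed: int

    @property
    def n_months(self) -> int:
        return len(self.months)


class DetectorError(ValueError):
    pass


def _as_frame(claims: Union[pd.DataFrame, Iterable[DispensationRecord]]
              ) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        missing = set(CLAIM_COLUMNS) - set(claims.columns)
        if missing:
            raise DetectorError(f"claims frame lacks columns {sorted(missing)}")
        return claims
    return records_to_frame(claims)


def _lut_map(series: pd.Series, key_fn, mapping: dict) -> np.ndarray:
    """Map a (possibly categorical) string column through ``mapping`` after
    normalising each distinct value with ``key_fn``; O(uniques) lookups."""
    codes, uniques = pd.factorize(series)
    lut = np.empty(len(uniques) + 1, dtype=object)
    lut[-1] = None  # factorize encodes missing values as -1
    for i, u in enumerate(uniques):
        lut[i] = mapping.get(key_fn("" if pd.isna(u) else str(u)))
    return lut[codes]


def _prepare(frame: pd.DataFrame, rules: RuleSet, window: StudyWindow
             ) -> tuple[pd.DataFrame, pd.Index]:
    """Classify, window-filter and factorise claims for fast merging.

    Returns (compact frame, patient-id labels); unclassified drugs are
    outside the study and silently dropped.
    """
    code_cls, code_sub, name_cls, name_sub = {}, {}, {}, {}
    for e in rules.catalog:
        canonical = e.code or e.name
        if e.code:
            code_cls[e.code.upper()] = e.class_label
            code_sub[e.code.upper()] = canonical
        for nm in (e.name, *e.aliases):
            if nm:
                name_cls[nm.lower()] = e.class_label
                name_sub[nm.lower()] = canonical

    cls = _lut_map(frame["drug_code"], str.upper, code_cls)
    sub = _lut_map(frame["drug_code"], str.upper, code_sub)
    unmatched = pd.isna(cls)
    if unmatched.any():  # code wins on conflict; names fill the gaps
        cls[unmatched] = _lut_map(frame["drug_name"], str.lower,
                                  name_cls)[unmatched]
        sub[unmatched] = _lut_map(frame["drug_name"], str.lower,
                                  name_sub)[unmatched]

    dates = pd.to_datetime(frame["dispense_date"])
    midx = (dates.dt.year * 12 + dates.dt.month - 1).astype("int32")
    keep = pd.notna(cls) & (midx >= window.start.index).to_numpy() \
        & (midx <= window.end.index).to_numpy()

    pid_codes, pid_labels = pd.factorize(frame.loc[keep, "patient_id"])
    rx_codes, rx_labels = pd.factorize(frame.loc[keep, "prescriber_id"])
    rx = rx_codes.astype("int64")
    if len(rx_labels):  # unknown prescriber -> sentinel that matches nothing
        labels_arr = np.asarray(rx_labels, dtype=object)
        empty_pos = np.flatnonzero(
            [(pd.isna(v) or str(v) == "") for v in labels_arr])
        for pos in empty_pos:
            rx[rx_codes == pos] = -1
    compact = pd.DataFrame({
        "pid": pid_codes,
        "midx": midx.to_numpy()[keep],
        "cls": cls[keep],
        "sub": sub[keep],
        "rx": rx,
        "dose": pd.to_numeric(frame.loc[keep, "daily_dose_mg"],
                              errors="coerce").to_numpy(dtype="float64"),
        "day": ((dates[keep] - pd.Timestamp("1970-01-01"))
                .dt.days.to_numpy(dtype="int32")),
    })
    return compact, pd.Index(pid_labels)


def flag_months_frame(claims: Union[pd.DataFrame,
                                    Iterable[DispensationRecord]],
                      rules: RuleSet, window: StudyWindow) -> pd.DataFrame:
    """Vectorised detection; returns one row per flagged patient-month.

    Columns: ``patient_id, rule_id, year, month, n_pairs, min_interval_days,
    co_prescribed``, canonically sorted so output is independent of input
    record order.
    """
    frame = _as_frame(claims)
    if frame.empty:
        return pd.DataFrame(columns=FLAG_COLUMNS)
    compact, pid_labels = _prepare(frame, rules, window)
    out = []
    for rule in rules.rules:
        a = compact[compact["cls"].isin(rule.side_a.labels)]
        if rule.min_daily_dose_mg is not None:
            a = a[a["dose"] >= rule.min_daily_dose_mg]
        b = compact[compact["cls"].isin(rule.side_b.labels)]
        if a.empty or b.empty:
            continue
        pairs = a.merge(b, on=["pid", "midx"], suffixes=("_a", "_b"))
        if rule.require_distinct_substance:
            # identical sides: keep each unordered record pair once
            pairs = pairs[pairs["sub_a"] < pairs["sub_b"]]
        if pairs.empty:
            continue
        interval = np.abs(pairs["day_a"].to_numpy()
                          - pairs["day_b"].to_numpy())
        co = (pairs["rx_a"].to_numpy() == pairs["rx_b"].to_numpy()) \
            & (pairs["rx_a"].to_numpy() >= 0)
        g = pd.DataFrame({"pid": pairs["pid"].to_numpy(),
                          "midx": pairs["midx"].to_numpy(),
                          "interval": interval, "co": co}) \
            .groupby(["pid", "midx"], sort=False) \
            .agg(n_pairs=("interval", "size"),
                 min_interval_days=("interval", "min"),
                 co_prescribed=("co", "any")) \
            .reset_index()
        g["rule_id"] = rule.rule_id
        out.append(g)
    if not out:
        return pd.DataFrame(columns=FLAG_COLUMNS)
    flags = pd.concat(out, ignore_index=True)
    flags["patient_id"] = np.asarray(pid_labels)[flags["pid"].to_numpy()]
    flags["year"] = flags["midx"] // 12
    flags["month"] = flags["midx"] % 12 + 1
    flags = flags[FLAG_COLUMNS].sort_values(
        ["rule_id", "patient_id", "year", "month"]).reset_index(drop=True)
    return flags


def flag_months(claims: Union[pd.DataFrame, Iterable[DispensationRecord]],
                rules: RuleSet, window: StudyWindow) -> list[MonthFlag]:
    """Record-object variant of :func:`flag_months_frame`."""
    flags = flag_months_frame(claims, rules, window)
    return [MonthFlag(patient_id=r.patient_id, rule_id=r.rule_id,
                      month=MonthKey(int(r.year), int(r.month)),
                      co_prescribed=bool(r.co_prescribed),
                      min_interval_days=int(r.min_interval_days),
                      n_pairs=int(r.n_pairs))
            for r in flags.itertuples(index=False)]


def _flags_frame(flags: Union[pd.DataFrame, Sequence[MonthFlag]]
                 ) -> pd.DataFrame:
    if isinstance(flags, pd.DataFrame):
        return flags
    return pd.DataFrame(
        [(f.patient_id, f.rule_id, f.month.year, f.month.month, f.n_pairs,
          f.min_interval_days, f.co_prescribed) for f in flags],
        columns=FLAG_COLUMNS)


def build_cases_frame(flags: Union[pd.DataFrame, Sequence[MonthFlag]],
                      policy: str = "any") -> pd.DataFrame:
    """Aggregate month flags into one case per (patient, rule).

    ``policy`` decides case-level attribution from month-level co-prescribing
    flags: ``any`` (default, most sensitive), ``all``, or ``majority``.
    Duplicate (patient, rule, month) flags indicate an upstream bug and raise.
    """
    if policy not in ATTRIBUTION_POLICIES:
        raise DetectorError(
            f"unknown attribution policy {policy!r}; "
            f"choose from {ATTRIBUTION_POLICIES}")
    f = _flags_frame(flags)
    if f.empty:
        return pd.DataFrame(columns=CASE_COLUMNS)
    keys = ["patient_id", "rule_id", "year", "month"]
    if f.duplicated(keys).any():
        dupe = f[f.duplicated(keys, keep=False)].iloc[0]
        raise DetectorError(
            "duplicate month flag for patient "
            f"{dupe.patient_id!r}, rule {dupe.rule_id!r}, "
            f"{int(dupe.year)}-{int(dupe.month):02d}")
    cases = f.groupby(["patient_id", "rule_id"], sort=False) \
        .agg(n_months=("month", "size"),
             patient_months_co_prescribed=("co_prescribed", "sum")) \
        .reset_index()
    n, k = cases["n_months"], cases["patient_months_co_prescribed"]
    if policy == "any":
        cases["case_co_prescribed"] = k > 0
    elif policy == "all":
        cases["case_co_prescribed"] = k == n
    else:  # majority of flagged months
        cases["case_co_prescribed"] = 2 * k > n
    cases = cases[CASE_COLUMNS].sort_values(
        ["rule_id", "patient_id"]).reset_index(drop=True)
    return cases


def build_cases(flags: Union[pd.DataFrame, Sequence[MonthFlag]],
                policy: str = "any") -> list[CaseRecord]:
    """Record-object variant of :func:`build_cases_frame` (keeps month sets)."""
    f = _flags_frame(flags)
    cases = build_cases_frame(f, policy=policy)
    months: dict[tuple[str, str], list[MonthKey]] = {}
    for r in f.itertuples(index=False):
        months.setdefault((r.patient_id, r.rule_id), []).append(
            MonthKey(int(r.year), int(r.month)))
    return [CaseRecord(patient_id=r.patient_id, rule_id=r.rule_id,
                       months=tuple(sorted(months[(r.patient_id, r.rule_id)])),
                       case_co_prescribed=bool(r.case_co_prescribed),
                       patient_months_co_prescribed=int(
                           r.patient_months_co_prescribed))
            for r in cases.itertuples(index=False)]
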