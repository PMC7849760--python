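"""Aggregate statistics of the pDDI screen.

Three summaries are produced from the detected cases:

* a **persistence table** — per rule, the histogram of cases by number of
  calendar months the interaction was present, with population prevalence
  percentages (count / population denominator);
* a **persistence summary** — per-rule mean months per case with a normal
  approximation 95% CI, mean ± 1.96·s/√n (s = sample standard deviation of
  the per-case month counts);
* an **attribution summary** — per-rule share of cases, and of
  patient-months, attributed to a single prescriber, plus overall weighted
  means (weighted by cases and by patient-months respectively).

Across-rule variation in persistence is tested with a tie-corrected
Kruskal-Wallis test (groups = rules, observations = months per case).
All accumulation is exact / full precision; rounding is display-only.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .claims_io import StudyWindow
from .detector import CASE_COLUMNS, CaseRecord

CasesLike = Union[pd.DataFrame, Sequence[CaseRecord]]


def display_round(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for table display."""
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def cases_frame(cases: CasesLike) -> pd.DataFrame:
    if isinstance(cases, pd.DataFrame):
        return cases
    return pd.DataFrame(
        [(c.patient_id, c.rule_id, c.n_months, c.case_co_prescribed,
          c.patient_months_co_prescribed) for c in cases],
        columns=CASE_COLUMNS)


@dataclass
class PersistenceTable:
    """Per-rule histogram of cases by months-with-pDDI (1..window length).

    ``counts`` is indexed by rule_id with integer columns 1..n_months.
    """
    counts: pd.DataFrame
    window: StudyWindow

    @classmethod
    def from_counts(cls, counts: Mapping[str, Sequence[int]],
                    window: StudyWindow) -> "PersistenceTable":
        frame = pd.DataFrame.from_dict(
            {r: list(v) for r, v in counts.items()}, orient="index",
            columns=range(1, window.n_months + 1)).astype("int64")
        frame.index.name = "rule_id"
        return cls(frame, window)

    @property
    def rule_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total_cases(self) -> int:
        return int(self.counts.to_numpy().sum())

    def rule_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def patient_months(self) -> pd.Series:
        """Σ_m m·counts[m] per rule — total flagged patient-months."""
        m = np.arange(1, self.window.n_months + 1)
        return (self.counts * m).sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def population_pct(self, x: Union[int, pd.Series]) -> Union[float, pd.Series]:
        """Prevalence % of the population denominator (full precision)."""
        return 100.0 * x / self.window.population_denominator

    def to_display(self) -> pd.DataFrame:
        """Counts with prevalence percentages, rounded to 2 decimals, plus a
        grand-total row — the shape the national screen publishes."""
        disp = self.counts.copy()
        disp["total"] = self.rule_totals()
        disp.loc["TOTAL"] = disp.sum(axis=0)
        pct = (100.0 * disp / self.window.population_denominator) \
            .map(lambda v: display_round(v, 2))
        out = disp.astype("int64").astype(str) + " (" \
            + pct.map(lambda v: f"{v:.2f}") + "%)"
        return out


def persistence_table(cases: CasesLike, window: StudyWindow,
                      rule_order: Optional[Sequence[str]] = None
                      ) -> PersistenceTable:
    """Histogram cases by n_months per rule (exact integer counts)."""
    f = cases_frame(cases)
    cols = range(1, window.n_months + 1)
    if f.empty:
        frame = pd.DataFrame(columns=cols, dtype="int64")
        frame.index.name = "rule_id"
        return PersistenceTable(frame, window)
    bad = f[(f["n_months"] < 1) | (f["n_months"] > window.n_months)]
    if len(bad):
        raise ValueError(
            f"case with n_months outside 1..{window.n_months}: "
            f"{bad.iloc[0].to_dict()}")
    pivot = pd.crosstab(f["rule_id"], f["n_months"]) \
        .reindex(columns=cols, fill_value=0).astype("int64")
    if rule_order is not None:
        pivot = pivot.reindex(index=[r for r in rule_order
                                     if r in pivot.index]
                              + [r for r in pivot.index
                                 if r not in rule_order])
        pivot = pivot.fillna(0).astype("int64")
    pivot.index.name = "rule_id"
    return PersistenceTable(pivot, window)


def persistence_summary(table: PersistenceTable) -> pd.DataFrame:
    """Per-rule mean months per case with a 95% normal-approximation CI.

    Returns a frame indexed by rule_id with columns ``n, mean_months,
    ci_low, ci_high, patient_months`` (full precision; round for display).
    Rules with zero cases are omitted with a warning.
    """
    m = np.arange(1, table.window.n_months + 1, dtype="float64")
    counts = table.counts.to_numpy(dtype="float64")
    n = counts.sum(axis=1)
    empty = n == 0
    if empty.any():
        warnings.warn("omitting rule(s) with zero cases: "
                      f"{list(table.counts.index[empty])}")
    keep = ~empty
    counts, n = counts[keep], n[keep]
    pm = counts @ m
    mean = pm / n
    sumsq = counts @ (m ** 2)
    # sample variance from the grouped histogram
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n > 1, (sumsq - n * mean ** 2) / (n - 1), 0.0)
    var = np.clip(var, 0.0, None)
    half = 1.96 * np.sqrt(var) / np.sqrt(n)
    return pd.DataFrame({
        "n": n.astype("int64"),
        "mean_months": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "patient_months": pm.astype("int64"),
    }, index=table.counts.index[keep])


@dataclass
class AttributionSummary:
    """Per-rule and overall same-prescriber attribution.

    ``per_rule`` is indexed by rule_id with columns ``n_cases,
    n_cases_same_prescriber, pct_cases_same_prescriber, n_patient_months,
    n_patient_months_same_prescriber, pct_patient_months_same_prescriber``.
    The overall means are weighted — by cases and by patient-months — so a
    rule's influence matches its size.
    """
    per_rule: pd.DataFrame
    case_weighted_pct: float
    patient_month_weighted_pct: float


def attribution_summary(cases: CasesLike,
                        rule_order: Optional[Sequence[str]] = None
                        ) -> AttributionSummary:
    f = cases_frame(cases)
    if f.empty:
        empty = pd.DataFrame(columns=[
            "n_cases", "n_cases_same_prescriber",
            "pct_cases_same_prescriber", "n_patient_months",
            "n_patient_months_same_prescriber",
            "pct_patient_months_same_prescriber"])
        return AttributionSummary(empty, float("nan"), float("nan"))
    g = f.groupby("rule_id", sort=False).agg(
        n_cases=("patient_id", "size"),
        n_cases_same_prescriber=("case_co_prescribed", "sum"),
        n_patient_months=("n_months", "sum"),
        n_patient_months_same_prescriber=(
            "patient_months_co_prescribed", "sum"))
    if rule_order is not None:
        g = g.reindex(index=[r for r in rule_order if r in g.index]
                      + [r for r in g.index if r not in rule_order])
    g["pct_cases_same_prescriber"] = \
        100.0 * g["n_cases_same_prescriber"] / g["n_cases"]
    g["pct_patient_months_same_prescriber"] = \
        100.0 * g["n_patient_months_same_prescriber"] / g["n_patient_months"]
    g = g[["n_cases", "n_cases_same_prescriber", "pct_cases_same_prescriber",
           "n_patient_months", "n_patient_months_same_prescriber",
           "pct_patient_months_same_prescriber"]]
    cw, pw = attribution_weighted_means(
        g["n_cases"], g["pct_cases_same_prescriber"],
        g["n_patient_months"], g["pct_patient_months_same_prescriber"])
    return AttributionSummary(g, cw, pw)


def attribution_weighted_means(n_cases: Sequence[float],
                               pct_cases: Sequence[float],
                               n_patient_months: Sequence[float],
                               pct_patient_months: Sequence[float]
                               ) -> tuple[float, float]:
    """Overall attribution means from per-rule columns: the case-weighted
    mean of case percentages and the patient-month-weighted mean of
    patient-month percentages."""
    n_cases = np.asarray(n_cases, dtype="float64")
    n_pm = np.asarray(n_patient_months, dtype="float64")
    cw = float(np.asarray(pct_cases, float) @ n_cases / n_cases.sum())
    pw = float(np.asarray(pct_patient_months, float) @ n_pm / n_pm.sum())
    return cw, pw


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    pvalue: float
    df: int


def kruskal_wallis(cases: CasesLike, method: str = "asymptotic",
                   n_permutations: int = 9999,
                   seed: Optional[int] = None) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis test of persistence across rules.

    Groups are the rules, observations the per-case month counts.  The
    default p-value uses the chi-square approximation with (groups - 1)
    degrees of freedom; ``method="permutation"`` instead estimates p by
    seeded label permutation (intended for toy inputs where the chi-square
    approximation is doubtful).
    """
    f = cases_frame(cases)
    groups = [g.to_numpy() for _, g in f.groupby("rule_id")["n_months"]
              if len(g)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs >=2 rules with >=1 case each")
    H, p = _sps.kruskal(*groups)
    H = float(H)
    df = len(groups) - 1
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        edges = np.cumsum(sizes)[:-1]
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            parts = np.split(pooled, edges)
            h_perm = _sps.kruskal(*parts).statistic
            if h_perm >= H - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    elif method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return KruskalResult(statistic=H, pvalue=float(p), df=df)


def kruskal_wallis_from_table(table: PersistenceTable) -> KruskalResult:
    """Kruskal-Wallis directly from a persistence histogram."""
    m = np.arange(1, table.window.n_months + 1)
    rows = []
    for rule_id, row in table.counts.iterrows():
        vals = np.repeat(m, row.to_numpy())
        if len(vals):
            rows.append(pd.DataFrame({"rule_id": rule_id, "n_months": vals}))
    return kruskal_wallis(pd.concat(rows, ignore_index=True)
                          .assign(patient_id="", case_co_prescribed=False,
                                  patient_months_co_prescribed=0))
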