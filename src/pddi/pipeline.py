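"""End-to-end screening runs: claims in, tables and summary out.

``run_screen`` chains read -> validate -> window filter -> month flags ->
cases -> statistics, writing the intermediate artifacts (flags, cases) and
the three result tables as CSV plus a ``summary.json`` with every headline
number at full precision and display rounding.  Stage counts are logged so a
run is auditable (read -> valid -> in-window -> flags -> cases).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import reference_data as ref
from .claims_io import (Dialect, StudyWindow, filter_window,
                        read_claims_frame)
from .detector import build_cases_frame, flag_months_frame
from .rulebook import RuleSet, load_ruleset
from .stats import (attribution_summary, display_round,
                    kruskal_wallis, persistence_summary, persistence_table)

log = logging.getLogger("pddi")


@dataclass
class RunConfig:
    input_path: Union[str, Path]
    out_dir: Union[str, Path]
    dialect: Optional[Dialect] = None
    rules: Union[str, Path] = "default"
    window: StudyWindow = field(
        default_factory=lambda: StudyWindow.year(ref.YEAR))
    attribution_policy: str = "any"
    max_reject_fraction: float = 0.10
    write_flags: bool = True


@dataclass
class ScreenResult:
    flags: pd.DataFrame
    cases: pd.DataFrame
    summary: dict
    out_dir: Path


def summarize(cases: pd.DataFrame, window: StudyWindow,
              ruleset: Optional[RuleSet] = None) -> dict:
    """All headline statistics of a run as one JSON-ready dict."""
    rule_order = ruleset.rule_ids if ruleset is not None else None
    table = persistence_table(cases, window, rule_order=rule_order)
    total = table.total_cases
    out: dict = {
        "window": {"start": list(table.window.start),
                   "end": list(table.window.end)},
        "population_denominator": window.population_denominator,
        "total_cases": total,
        "unique_patients": int(cases["patient_id"].nunique())
        if len(cases) else 0,
        "total_patient_months": int(table.patient_months().sum()),
    }
    out["pct_population_cases"] = float(table.population_pct(total))
    out["pct_population_cases_display"] = display_round(
        out["pct_population_cases"], 2)
    # a patient with two pDDI types counts twice in total_cases; the
    # unique-patient prevalence below does not conflate the two
    out["pct_population_unique_patients"] = float(
        table.population_pct(out["unique_patients"]))
    if total:
        col = table.column_totals()
        out["pct_cases_single_month"] = float(100.0 * col.get(1, 0) / total)
        out["pct_cases_up_to_3_months"] = float(
            100.0 * sum(col.get(m, 0) for m in (1, 2, 3)) / total)
    per_rule = {}
    summary_frame = persistence_summary(table) if total else pd.DataFrame()
    attr = attribution_summary(cases, rule_order=rule_order)
    for rule_id in table.rule_ids:
        n = int(table.rule_totals()[rule_id])
        entry = {
            "n_cases": n,
            "pct_population": float(table.population_pct(n)),
            "pct_of_total_cases": float(100.0 * n / total) if total else 0.0,
            "histogram": [int(x) for x in table.counts.loc[rule_id]],
        }
        if rule_id in summary_frame.index:
            row = summary_frame.loc[rule_id]
            entry.update(
                mean_months=float(row["mean_months"]),
                ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
                patient_months=int(row["patient_months"]))
        if rule_id in attr.per_rule.index:
            row = attr.per_rule.loc[rule_id]
            entry.update(
                pct_cases_same_prescriber=float(
                    row["pct_cases_same_prescriber"]),
                pct_patient_months_same_prescriber=float(
                    row["pct_patient_months_same_prescriber"]))
        per_rule[rule_id] = entry
    out["per_rule"] = per_rule
    if len(attr.per_rule):
        out["pct_cases_same_prescriber_weighted"] = attr.case_weighted_pct
        out["pct_patient_months_same_prescriber_weighted"] = \
            attr.patient_month_weighted_pct
    n_rules_nonempty = int((table.rule_totals() > 0).sum())
    if n_rules_nonempty >= 2:
        kw = kruskal_wallis(cases)
        out["kruskal_wallis"] = {"H": kw.statistic, "p": kw.pvalue,
                                 "df": kw.df}
    return out


def write_outputs(flags: pd.DataFrame, cases: pd.DataFrame,
                  summary: dict, window: StudyWindow, out_dir: Path,
                  ruleset: Optional[RuleSet] = None,
                  write_flags: bool = True) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if write_flags:
        flags.to_csv(out_dir / "flags.csv", index=False)
    cases.to_csv(out_dir / "cases.csv", index=False)
    rule_order = ruleset.rule_ids if ruleset is not None else None
    table = persistence_table(cases, window, rule_order=rule_order)
    table.to_display().to_csv(out_dir / "table3.csv")
    attr = attribution_summary(cases, rule_order=rule_order)
    attr.per_rule.to_csv(out_dir / "table4.csv")
    if table.total_cases:
        persistence_summary(table).to_csv(out_dir / "fig1.csv")
    else:
        pd.DataFrame(columns=["n", "mean_months", "ci_low", "ci_high",
                              "patient_months"]).to_csv(out_dir / "fig1.csv")
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)


def run_screen(config: RunConfig) -> ScreenResult:
    ruleset = load_ruleset(config.rules)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = read_claims_frame(
        config.input_path, config.dialect,
        max_reject_fraction=config.max_reject_fraction,
        rejects_path=out_dir / "rejects.csv")
    log.info("read %d rows, %d valid, %d rejected",
             report.n_read, report.n_valid, report.n_rejected)
    claims = filter_window(report.frame, config.window)
    log.info("%d records inside the study window", len(claims))
    flags = flag_months_frame(claims, ruleset, config.window)
    log.info("%d flagged patient-months", len(flags))
    cases = build_cases_frame(flags, policy=config.attribution_policy)
    log.info("%d cases", len(cases))
    summary = summarize(cases, config.window, ruleset)
    summary["stage_counts"] = {
        "read": report.n_read, "valid": report.n_valid,
        "rejected": report.n_rejected, "in_window": len(claims),
        "month_flags": len(flags), "cases": len(cases),
    }
    write_outputs(flags, cases, summary, config.window, out_dir,
                  ruleset, config.write_flags)
    return ScreenResult(flags=flags, cases=cases, summary=summary,
                        out_dir=out_dir)
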