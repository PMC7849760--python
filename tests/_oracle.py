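"""Independent reference implementations used only as test oracles.

Deliberately naive: plain-Python quadratic pair enumeration for month
flagging, and an explicit average-rank computation for Kruskal-Wallis.
They share no code path with the package implementation.
"""
from collections import defaultdict

from pddi.claims_io import DispensationRecord, StudyWindow
from pddi.rulebook import RuleSet


def _classify_token(ruleset: RuleSet, code: str, name: str):
    """(class_label, canonical substance) by linear catalog scan."""
    for e in ruleset.catalog:
        if code and e.code and code.upper() == e.code.upper():
            return e.class_label, (e.code or e.name)
    for e in ruleset.catalog:
        for nm in (e.name, *e.aliases):
            if name and nm and name.lower() == nm.lower():
                return e.class_label, (e.code or e.name)
    return None, None


def brute_force_flags(records: list[DispensationRecord], ruleset: RuleSet,
                      window: StudyWindow):
    """All-pairs enumeration per patient-month.

    Returns {(patient_id, rule_id, year, month):
             (n_pairs, min_interval_days, co_prescribed)}.
    """
    by_pm = defaultdict(list)
    for r in records:
        cls, sub = _classify_token(ruleset, r.drug_code, r.drug_name)
        if cls is None:
            continue
        mk = r.month
        if mk not in window:
            continue
        by_pm[(r.patient_id, mk)].append((cls, sub, r))

    out = {}
    for (pid, mk), recs in by_pm.items():
        for rule in ruleset.rules:
            pairs = []
            for (cls_a, sub_a, a) in recs:
                if cls_a not in rule.side_a.labels:
                    continue
                if rule.min_daily_dose_mg is not None and (
                        a.daily_dose_mg is None
                        or a.daily_dose_mg < rule.min_daily_dose_mg):
                    continue
                for (cls_b, sub_b, b) in recs:
                    if b is a or cls_b not in rule.side_b.labels:
                        continue
                    if rule.require_distinct_substance:
                        if not sub_a < sub_b:  # also dedupes unordered pairs
                            continue
                    pairs.append((a, b))
            if not pairs:
                continue
            gap = min(abs((a.dispense_date - b.dispense_date).days)
                      for a, b in pairs)
            co = any(a.prescriber_id and a.prescriber_id == b.prescriber_id
                     for a, b in pairs)
            out[(pid, rule.rule_id, mk.year, mk.month)] = \
                (len(pairs), gap, co)
    return out


def kruskal_by_hand(groups):
    """Tie-corrected Kruskal-Wallis H from explicit average ranks."""
    pooled = sorted(v for g in groups for v in g)
    n = len(pooled)
    # average rank of each distinct value
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        ranks[pooled[i]] = (i + 1 + j) / 2  # mean of ranks i+1..j
        i = j
    grand = (n + 1) / 2
    h = 12 / (n * (n + 1)) * sum(
        len(g) * (sum(ranks[v] for v in g) / len(g) - grand) ** 2
        for g in groups)
    ties = 0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t ** 3 - t
    correction = 1 - ties / (n ** 3 - n)
    return h / correction if correction else float("nan")
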