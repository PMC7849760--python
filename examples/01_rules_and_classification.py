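"""Load the packaged interaction rule set and classify some drugs.

The rule set carries the nine analgesic interaction pairs of the 2018
Polish national screen: a flat catalog (substance -> drug class) plus the
class pairs, severity categories (C = monitor therapy, D = consider
therapy modification) and per-rule conditions.
"""
from pddi import classify, load_ruleset

rs = load_ruleset("default")
print(f"{len(rs.rules)} rules over {len(rs.catalog)} substances\n")

for rule in rs.rules:
    cond = []
    if rule.min_daily_dose_mg:
        cond.append(f"daily dose >= {rule.min_daily_dose_mg:g} mg")
    if rule.require_distinct_substance:
        cond.append("two different substances")
    print(f"  [{rule.category}] {rule.display_name}"
          + (f"  ({'; '.join(cond)})" if cond else ""))

print()
for token in ["ibuprofen", "M01AE01", "tramadol", "codeine", "omeprazole"]:
    print(f"  {token!r:14s} -> {classify(rs, token)}")

# tramadol is screened as its own class (weak opioid with a dose condition),
# while codeine is grouped with the strong opioids; drugs outside the study
# rosters (omeprazole) classify to None and are simply ignored.
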