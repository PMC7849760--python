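"""Drug catalog and interaction rules for the analgesic pDDI screen.

A :class:`RuleSet` bundles a flat drug catalog (substance -> drug class) with
a list of :class:`InteractionRule` objects, each pairing two class selectors
with a severity category and optional conditions (a minimum daily dose on one
side; a distinct-substance requirement for self-pair rules such as
NSAID + NSAID).  The packaged default (``load_ruleset("default")``) carries
the nine analgesic interaction pairs screened in the 2018 Polish national
dispensation analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

#: Closed vocabulary of drug classes the screen understands.
CLASS_LABELS = frozenset({
    "NSAID", "TRAMADOL", "OPIOID", "BENZODIAZEPINE", "GABAPENTINOID",
    "GC", "ANTIPLATELET", "ANTIHYPERTENSIVE_ACEI", "ANTIHYPERTENSIVE_ARB",
    "ANTIHYPERTENSIVE_BB", "SSRI", "SNRI", "OAC",
})

#: Severity categories: C = monitor therapy, D = consider therapy
#: modification, X = avoid combination.
CATEGORIES = frozenset({"C", "D", "X"})


class RulebookError(ValueError):
    """A rule file violated the documented schema."""


@dataclass(frozen=True)
class DrugEntry:
    """One substance in the catalog.

    ``code`` is an ATC-style identifier, ``name`` a lowercase substance name,
    ``aliases`` alternative spellings that should classify the same way.
    """
    code: str
    name: str
    class_label: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise RulebookError(
                f"catalog entry {self.name!r}: unknown class "
                f"{self.class_label!r}; allowed: {sorted(CLASS_LABELS)}"
            )
        if not self.code and not self.name:
            raise RulebookError("catalog entry needs a code or a name")


@dataclass(frozen=True)
class ClassSelector:
    """A set of class labels treated as one side of an interaction rule."""
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise RulebookError("a rule side must select at least one class")
        unknown = set(self.labels) - CLASS_LABELS
        if unknown:
            raise RulebookError(
                f"unknown class label(s) {sorted(unknown)}; "
                f"allowed: {sorted(CLASS_LABELS)}"
            )

    def __contains__(self, label: str) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class InteractionRule:
    """One screened drug-drug interaction pair.

    The two sides are unordered for matching; ``side_a`` is the side a
    ``min_daily_dose_mg`` condition applies to (the tramadol rule only).
    ``require_distinct_substance`` is needed when both sides select the same
    class, so that two fills of one substance never pair with themselves.
    ``category`` is carried as metadata and never filters detection.
    """
    rule_id: str
    side_a: ClassSelector
    side_b: ClassSelector
    category: str
    min_daily_dose_mg: Optional[float] = None
    require_distinct_substance: bool = False
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RulebookError(
                f"rule {self.rule_id!r}: category must be one of C, D, X"
            )
        if self.side_a == self.side_b and not self.require_distinct_substance:
            raise RulebookError(
                f"rule {self.rule_id!r}: identical sides require "
                "require_distinct_substance: true"
            )
        if self.min_daily_dose_mg is not None and self.min_daily_dose_mg < 0:
            raise RulebookError(
                f"rule {self.rule_id!r}: min_daily_dose_mg must be >= 0"
            )


@dataclass
class RuleSet:
    """An ordered list of interaction rules plus the catalog they refer to."""
    rules: list[InteractionRule]
    catalog: list[DrugEntry]
    _by_code: dict[str, DrugEntry] = field(init=False, repr=False)
    _by_name: dict[str, DrugEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise RulebookError("rule_ids must be unique")
        self._by_code = {}
        self._by_name = {}
        for e in self.catalog:
            if e.code:
                key = e.code.upper()
                if key in self._by_code:
                    raise RulebookError(f"duplicate catalog code {e.code!r}")
                self._by_code[key] = e
            for nm in (e.name, *e.aliases):
                if not nm:
                    continue
                key = nm.lower()
                if key in self._by_name:
                    raise RulebookError(f"duplicate catalog name {nm!r}")
                self._by_name[key] = e
        have = {e.class_label for e in self.catalog}
        for r in self.rules:
            missing = (r.side_a.labels | r.side_b.labels) - have
            if missing:
                raise RulebookError(
                    f"rule {r.rule_id!r} references class(es) with no "
                    f"catalog entry: {sorted(missing)}"
                )

    @property
    def rule_ids(self) -> list[str]:
        return [r.rule_id for r in self.rules]

    def classes(self) -> dict[str, list[str]]:
        """Class label -> sorted substance names (the roster)."""
        out: dict[str, list[str]] = {}
        for e in self.catalog:
            out.setdefault(e.class_label, []).append(e.name)
        return {k: sorted(v) for k, v in out.items()}


def classify(catalog: Union[RuleSet, Iterable[DrugEntry]],
             token: str) -> Optional[str]:
    """Map a drug code or name to its study class label, or ``None``.

    Matching is case-insensitive, code first, then name/alias.  Drugs not in
    any roster are simply outside the study.
    """
    entry = lookup(catalog, token)
    return entry.class_label if entry is not None else None


def lookup(catalog: Union[RuleSet, Iterable[DrugEntry]],
           token: str) -> Optional[DrugEntry]:
    """Resolve a code or name to its catalog entry (``None`` if absent)."""
    if not token:
        return None
    if not isinstance(catalog, RuleSet):
        catalog = RuleSet(rules=[], catalog=list(catalog))
    return (catalog._by_code.get(token.upper())
            or catalog._by_name.get(token.lower()))


def _parse_ruleset(doc: dict) -> RuleSet:
    if not isinstance(doc, dict) or "catalog" not in doc or "rules" not in doc:
        raise RulebookError(
            "rule file must be a mapping with 'catalog' and 'rules' sections"
        )
    catalog = []
    for raw in doc["catalog"]:
        try:
            catalog.append(DrugEntry(
                code=str(raw.get("code", "") or ""),
                name=str(raw.get("name", "") or "").lower(),
                class_label=str(raw["class"]),
                aliases=tuple(str(a).lower() for a in raw.get("aliases", [])),
            ))
        except KeyError as exc:
            raise RulebookError(f"catalog entry missing field {exc}") from exc
    rules = []
    for raw in doc["rules"]:
        try:
            dose = raw.get("min_daily_dose_mg")
            rules.append(InteractionRule(
                rule_id=str(raw["rule_id"]),
                side_a=ClassSelector(frozenset(raw["side_a"])),
                side_b=ClassSelector(frozenset(raw["side_b"])),
                category=str(raw["category"]),
                min_daily_dose_mg=float(dose) if dose is not None else None,
                require_distinct_substance=bool(
                    raw.get("require_distinct_substance", False)),
                display_name=str(raw.get("display_name", raw["rule_id"])),
            ))
        except KeyError as exc:
            raise RulebookError(f"rule entry missing field {exc}") from exc
    return RuleSet(rules=rules, catalog=catalog)


def load_ruleset(path: Union[str, Path] = "default") -> RuleSet:
    """Load a rule file (YAML or JSON), or the packaged default rule set."""
    if str(path) == "default":
        text = (resources.files("pddi") / "data" / "default_rules.yaml") \
            .read_text(encoding="utf-8")
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"rule file not found: {p}")
        text = p.read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise RulebookError(f"rule file does not parse: {exc}") from exc
    return _parse_ruleset(doc)


def dump_ruleset(ruleset: RuleSet) -> str:
    """Serialize a RuleSet back to the documented YAML schema."""
    doc = {
        "catalog": [
            {"code": e.code, "name": e.name, "class": e.class_label,
             **({"aliases": list(e.aliases)} if e.aliases else {})}
            for e in ruleset.catalog
        ],
        "rules": [
            {
                "rule_id": r.rule_id,
                "display_name": r.display_name,
                "side_a": sorted(r.side_a.labels),
                "side_b": sorted(r.side_b.labels),
                "category": r.category,
                **({"min_daily_dose_mg": r.min_daily_dose_mg}
                   if r.min_daily_dose_mg is not None else {}),
                **({"require_distinct_substance": True}
                   if r.require_distinct_substance else {}),
            }
            for r in ruleset.rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
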