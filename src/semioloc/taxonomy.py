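"""Pattern-based semiology taxonomy.

Free-text ictal descriptions ("lip smacking and chewing", "dystonic posturing
of right hand") are mapped onto a fixed category inventory by case-insensitive
word-boundary regular expressions.  Two safeguards prevent the classic
clinical-text pitfalls:

* **string similarity** — a match is suppressed when the matched span is part
  of a longer excluded term (so "dystonic" never triggers the Tonic category,
  and "myoclonic" never triggers a clonic-derived one);
* **negation** — a match is suppressed when a negation cue ("no", "not",
  "without", "denies", "absence of") occurs within a configurable token window
  before the span, with clause punctuation acting as a scope barrier.

Postictal and asymptomatic categories exist so that stimulation-study records
can be represented, but they are stripped before any localization analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "CategoryRule",
    "Taxonomy",
    "TaxonomyDefinitionError",
    "load_taxonomy",
    "default_taxonomy",
    "classify_text",
    "classify_records",
    "strip_nonictal",
]

KINDS = ("ictal", "postictal", "asymptomatic")

NEGATION_CUES = ("no", "not", "without", "denies", "denied", "absence of")

# punctuation that terminates the backward scan for a negation cue
_CLAUSE_BARRIER = re.compile(r"[,;.:!?]")
_TOKEN = re.compile(r"\S+")


class TaxonomyDefinitionError(ValueError):
    """Raised for malformed or duplicated taxonomy definitions."""


@dataclass(frozen=True)
class CategoryRule:
    name: str
    kind: str
    include_patterns: tuple[str, ...]
    exclude_patterns: tuple[str, ...] = ()
    negation_window: int = 3

    def __post_init__(self):
        if self.kind not in KINDS:
            raise TaxonomyDefinitionError(f"{self.name}: unknown kind {self.kind!r}")
        if not self.include_patterns:
            raise TaxonomyDefinitionError(f"{self.name}: include patterns must be non-empty")
        if set(self.include_patterns) & set(self.exclude_patterns):
            raise TaxonomyDefinitionError(
                f"{self.name}: exclude patterns must be disjoint from include patterns"
            )

    def compiled_includes(self) -> tuple[re.Pattern, ...]:
        return tuple(re.compile(rf"\b(?:{p})\b", re.IGNORECASE) for p in self.include_patterns)

    def compiled_excludes(self) -> tuple[re.Pattern, ...]:
        return tuple(re.compile(rf"\b(?:{p})\b", re.IGNORECASE) for p in self.exclude_patterns)


@dataclass(frozen=True)
class Taxonomy:
    categories: tuple[CategoryRule, ...]
    version: str = "unversioned"

    def __post_init__(self):
        names = [c.name for c in self.categories]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TaxonomyDefinitionError(f"duplicate category name(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def rule(self, name: str) -> CategoryRule:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def kind_of(self, name: str) -> str:
        return self.rule(name).kind

    def with_category(self, rule: CategoryRule) -> "Taxonomy":
        return Taxonomy(categories=self.categories + (rule,), version=self.version)


def load_taxonomy(path=None) -> Taxonomy:
    """Load a taxonomy definition from YAML/JSON (shipped default if *path* is None)."""
    if path is None:
        text = resources.files("semioloc.data").joinpath("semiodict.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    cats = spec.get("categories")
    if not isinstance(cats, dict):
        raise TaxonomyDefinitionError("taxonomy file must carry a 'categories' mapping")
    rules = []
    for name, body in cats.items():
        rules.append(
            CategoryRule(
                name=str(name),
                kind=body.get("kind", "ictal"),
                include_patterns=tuple(body.get("include") or ()),
                exclude_patterns=tuple(body.get("exclude") or ()),
                negation_window=int(body.get("negation_window", 3)),
            )
        )
    return Taxonomy(categories=tuple(rules), version=str(spec.get("version", "unversioned")))


def default_taxonomy() -> Taxonomy:
    return load_taxonomy(None)


def _negated(text: str, span_start: int, window: int) -> bool:
    """True if a negation cue lies within *window* tokens before the span,
    with no clause punctuation between cue and span."""
    if window <= 0:
        return False
    prefix = text[:span_start]
    # scope barrier: only scan back to the last clause punctuation
    barrier = None
    for m in _CLAUSE_BARRIER.finditer(prefix):
        barrier = m.end()
    if barrier is not None:
        prefix = prefix[barrier:]
    tokens = _TOKEN.findall(prefix.lower())
    tail = tokens[-window:]
    joined = " ".join(tail)
    for cue in NEGATION_CUES:
        if " " in cue:
            if cue in joined:
                return True
        elif cue in tail:
            return True
    return False


def _inside_excluded(text: str, start: int, end: int, excludes: Sequence[re.Pattern]) -> bool:
    for pat in excludes:
        for m in pat.finditer(text):
            if m.start() <= start and end <= m.end():
                return True
    return False


def classify_text(taxonomy: Taxonomy, text: str) -> set[str]:
    """All category labels whose patterns match *text*.

    Case- and surrounding-whitespace-insensitive.  An empty set means the text
    is unclassified.
    """
    text = text.strip()
    if not text:
        return set()
    labels: set[str] = set()
    for rule in taxonomy.categories:
        excludes = rule.compiled_excludes()
        for pat in rule.compiled_includes():
            hit = False
            for m in pat.finditer(text):
                if _inside_excluded(text, m.start(), m.end(), excludes):
                    continue
                if _negated(text, m.start(), rule.negation_window):
                    continue
                hit = True
                break
            if hit:
                labels.add(rule.name)
                break
    return labels


def classify_records(records: Iterable, taxonomy: Taxonomy) -> list:
    """Assign categories to records from their free text.

    Records that already carry a category are passed through unchanged.  A
    text matching several categories yields one record per category, since the
    downstream unit of analysis is a single patient-semiology.  Unclassifiable
    records are dropped (they carry no analysable category).
    """
    out = []
    for rec in records:
        if rec.semiology_category:
            out.append(rec)
            continue
        labels = classify_text(taxonomy, rec.semiology_text or "")
        for label in sorted(labels):
            out.append(replace(rec, semiology_category=label))
    return out


def strip_nonictal(records: Iterable, taxonomy: Taxonomy) -> list:
    """Drop records whose category is postictal or asymptomatic.

    Categories unknown to the taxonomy are retained (treated as ictal)."""
    out = []
    for rec in records:
        cat = rec.semiology_category
        try:
            kind = taxonomy.kind_of(cat) if cat else "ictal"
        except KeyError:
            kind = "ictal"
        if kind == "ictal":
            out.append(rec)
    return out
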