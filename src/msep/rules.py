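"""Rule-based per-condition status classification of sentences.

Each condition carries a set of keyword patterns plus cue lexica (negation,
family context, cessation, relapse).  A sentence with no keyword match is
``unknown``.  Otherwise the decision is scoped to the clause containing the
first keyword occurrence (a clause is a maximal run between clause
delimiters), with cue precedence

    family > relapse > cessation > negation > bare keyword

Family cues either assert the condition (for conditions that are themselves
familial, e.g. family history of cancer) or suppress it to ``unknown`` (the
relative, not the patient, has it).  A relapse cue overrides cessation —
"reprise récente malgré un sevrage" means the patient is an active smoker.
Cessation maps to ``former`` where that status exists (smoking), ``absent``
otherwise.  A negation cue counts only when it precedes the keyword within
the clause.

Matching is case-insensitive and diacritic-sensitive.  The shipped French
lexica for the six study conditions are reconstructions for testing and
demonstration, editable as YAML config files.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .corpus import Sentence

__all__ = [
    "STATUS_LABELS",
    "CONDITION_IS_FAMILIAL",
    "FAMILIAL_MEANS_UNKNOWN",
    "RuleSet",
    "RuleDecision",
    "Preannotation",
    "classify_with_rules",
    "preannotate",
    "load_ruleset",
    "builtin_ruleset",
    "builtin_conditions",
]

#: The four possible per-condition statuses.  "former" is valid only for
#: conditions that declare it (smoking in the study setting).
STATUS_LABELS = ("present", "absent", "former", "unknown")

CONDITION_IS_FAMILIAL = "condition_is_familial"
FAMILIAL_MEANS_UNKNOWN = "familial_means_unknown"

_DEFAULT_DELIMITERS = (",", ";", ":", "mais", "et")


@dataclass(frozen=True)
class RuleSet:
    """Keyword patterns and cue lexica for one medical condition."""

    condition: str
    keyword_patterns: tuple[str, ...]
    negation_cues: tuple[str, ...] = ()
    family_cues: tuple[str, ...] = ()
    cessation_cues: tuple[str, ...] = ()
    relapse_cues: tuple[str, ...] = ()
    clause_delimiters: tuple[str, ...] = _DEFAULT_DELIMITERS
    family_semantics: str = FAMILIAL_MEANS_UNKNOWN
    has_former: bool = False

    def __post_init__(self) -> None:
        if not self.keyword_patterns:
            raise ValueError(f"ruleset {self.condition!r}: keyword_patterns must be non-empty")
        if self.has_former and not self.cessation_cues:
            raise ValueError(
                f"ruleset {self.condition!r}: 'former' is reachable only with cessation cues"
            )
        if self.family_semantics not in (CONDITION_IS_FAMILIAL, FAMILIAL_MEANS_UNKNOWN):
            raise ValueError(f"unknown family_semantics {self.family_semantics!r}")

    @property
    def label_set(self) -> tuple[str, ...]:
        if self.has_former:
            return ("present", "absent", "former", "unknown")
        return ("present", "absent", "unknown")


@dataclass(frozen=True)
class RuleDecision:
    """Audit trail for one rule classification."""

    label: str
    matched_keyword: tuple[int, int] | None
    fired_cues: tuple[tuple[str, str, tuple[int, int]], ...] = ()


@dataclass
class Preannotation:
    """Per-sentence rule decisions plus a per-label count summary."""

    decisions: dict[str, RuleDecision]
    counts: dict[str, int] = field(default_factory=dict)


@lru_cache(maxsize=256)
def _compile_keywords_cached(patterns: tuple[str, ...]) -> tuple[re.Pattern, ...]:
    return tuple(re.compile(p, re.IGNORECASE) for p in patterns)


def _compile_keywords(rules: RuleSet) -> tuple[re.Pattern, ...]:
    return _compile_keywords_cached(rules.keyword_patterns)


@lru_cache(maxsize=4096)
def _cue_pattern(cue: str) -> re.Pattern:
    # Word-bounded literal match.  Lookarounds only apply where the cue edge
    # is itself a word character ("pas d'" must still match before a vowel).
    pre = r"(?<!\w)" if cue and (cue[0].isalnum() or cue[0] == "_") else ""
    post = r"(?!\w)" if cue and (cue[-1].isalnum() or cue[-1] == "_") else ""
    return re.compile(pre + re.escape(cue) + post, re.IGNORECASE)


def _clause_bounds(text: str, pos: int, delimiters: Sequence[str]) -> tuple[int, int]:
    """Bounds of the maximal delimiter-free run containing position ``pos``."""
    cuts: list[tuple[int, int]] = []
    for d in delimiters:
        if d.isalpha():
            pat = re.compile(r"(?<!\w)" + re.escape(d) + r"(?!\w)", re.IGNORECASE)
        else:
            pat = re.compile(re.escape(d))
        cuts.extend(m.span() for m in pat.finditer(text))
    lo, hi = 0, len(text)
    for a, b in cuts:
        if b <= pos and b > lo:
            lo = b
        if a > pos and a < hi:
            hi = a
    return lo, hi


def classify_with_rules(sentence: Sentence, rules: RuleSet) -> RuleDecision:
    """Classify one sentence for one condition.  Total: always returns a label."""
    text = sentence.text
    best: tuple[int, int] | None = None
    for pat in _compile_keywords(rules):
        m = pat.search(text)
        if m and (best is None or m.start() < best[0]):
            best = m.span()
    if best is None:
        return RuleDecision(label="unknown", matched_keyword=None)

    lo, hi = _clause_bounds(text, best[0], rules.clause_delimiters)
    clause = text[lo:hi]

    fired: list[tuple[str, str, tuple[int, int]]] = []
    hits: dict[str, list[tuple[int, int]]] = {}
    for cue_type, lexicon in (
        ("family", rules.family_cues),
        ("relapse", rules.relapse_cues),
        ("cessation", rules.cessation_cues),
        ("negation", rules.negation_cues),
    ):
        spans = []
        for cue in sorted(lexicon):
            for m in _cue_pattern(cue).finditer(clause):
                span = (lo + m.start(), lo + m.end())
                spans.append(span)
                fired.append((cue, cue_type, span))
        spans.sort()
        hits[cue_type] = spans

    fired.sort(key=lambda f: (f[2], f[1], f[0]))
    fired_t = tuple(fired)

    if hits["family"]:
        if rules.family_semantics == CONDITION_IS_FAMILIAL:
            return RuleDecision("present", best, fired_t)
        return RuleDecision("unknown", best, fired_t)
    if hits["relapse"]:
        return RuleDecision("present", best, fired_t)
    if hits["cessation"]:
        label = "former" if rules.has_former else "absent"
        return RuleDecision(label, best, fired_t)
    if any(span[0] < best[0] for span in hits["negation"]):
        return RuleDecision("absent", best, fired_t)
    return RuleDecision("present", best, fired_t)


def preannotate(sentences: Iterable[Sentence], rules: RuleSet) -> Preannotation:
    """Apply the rule classifier to every sentence; order-independent."""
    decisions = {s.sent_id: classify_with_rules(s, rules) for s in sentences}
    counts = Counter(d.label for d in decisions.values())
    return Preannotation(decisions=decisions, counts={l: counts.get(l, 0) for l in STATUS_LABELS})


# ---------------------------------------------------------------------------
# RuleSet files
# ---------------------------------------------------------------------------


def _ruleset_from_mapping(rec: Mapping) -> RuleSet:
    return RuleSet(
        condition=rec["condition"],
        keyword_patterns=tuple(rec["keyword_patterns"]),
        negation_cues=tuple(rec.get("negation_cues", ())),
        family_cues=tuple(rec.get("family_cues", ())),
        cessation_cues=tuple(rec.get("cessation_cues", ())),
        relapse_cues=tuple(rec.get("relapse_cues", ())),
        clause_delimiters=tuple(rec.get("clause_delimiters", _DEFAULT_DELIMITERS)),
        family_semantics=rec.get("family_semantics", FAMILIAL_MEANS_UNKNOWN),
        has_former=bool(rec.get("has_former", False)),
    )


def load_ruleset(path: str | Path) -> RuleSet:
    """Load a RuleSet from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    rec = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _ruleset_from_mapping(rec)


_LEXICA_DIR = Path(__file__).parent / "data" / "lexica"


def builtin_conditions() -> list[str]:
    return sorted(p.stem for p in _LEXICA_DIR.glob("*.yaml"))


def builtin_ruleset(condition: str) -> RuleSet:
    """Shipped reconstruction lexicon for one of the six study conditions."""
    path = _LEXICA_DIR / f"{condition}.yaml"
    if not path.exists():
        raise KeyError(f"no built-in ruleset for {condition!r}; have {builtin_conditions()}")
    return load_ruleset(path)
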