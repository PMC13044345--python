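"""Annotation records, inter-annotator agreement, correction, time accounting.

Two annotators label the qualified sentences; agreement on the doubly
annotated overlap is measured with Cohen's kappa

    kappa = (Po - Pe) / (1 - Pe)

where Po is the observed agreement and Pe the agreement expected by chance
from the two annotators' label marginals.  A kappa threshold (0.8 in the
study setting) gates whether the annotations are trusted; failures trigger
disagreement analysis and a term-driven correction round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Sentence, normalized_key

__all__ = [
    "AnnotationRecord",
    "AgreementResult",
    "CorrectionPlan",
    "AnnotationError",
    "cohen_kappa",
    "agreement_gate",
    "find_disagreements",
    "select_for_revision",
    "apply_corrections",
    "annotation_time_summary",
    "read_annotations",
    "write_annotations",
]


class AnnotationError(ValueError):
    """Raised for inconsistent annotation inputs."""


@dataclass(frozen=True)
class AnnotationRecord:
    sent_id: str
    annotator_id: str
    condition: str
    label: str
    duration_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_seconds < 0:
            raise AnnotationError(
                f"record {self.sent_id}/{self.annotator_id}: negative duration"
            )


@dataclass
class AgreementResult:
    kappa: float
    po: float
    pe: float
    n_items: int
    contingency: pd.DataFrame


@dataclass
class CorrectionPlan:
    """Term-driven selection of sentences for revision after a failed gate."""

    ambiguous_terms: list[str]
    guideline_version: str = "v2"
    selected_sent_ids: list[str] = field(default_factory=list)


def _labels_by_sentence(
    records: Iterable[AnnotationRecord], condition: str
) -> dict[str, str]:
    out: dict[str, str] = {}
    for r in records:
        if r.condition != condition:
            continue
        if r.sent_id in out:
            raise AnnotationError(
                f"duplicate record for sentence {r.sent_id!r} by {r.annotator_id!r}"
            )
        out[r.sent_id] = r.label
    return out


def _paired_labels(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    condition: str,
) -> tuple[list[str], list[str], list[str]]:
    a = _labels_by_sentence(records_a, condition)
    b = _labels_by_sentence(records_b, condition)
    if not a or not b:
        raise AnnotationError(f"no annotations for condition {condition!r}")
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise AnnotationError(
            f"annotators labeled different sentence sets for {condition!r}: "
            f"only annotator A {only_a[:5]}, only annotator B {only_b[:5]}"
        )
    ids = list(a)  # insertion order of annotator A's records
    return ids, [a[i] for i in ids], [b[i] for i in ids]


def cohen_kappa(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    condition: str,
) -> AgreementResult:
    """Chance-corrected agreement on the doubly-annotated overlap.

    Degenerate convention: when Pe = 1 (both annotators constant on the same
    label), kappa is 1 if Po = 1 else 0.
    """
    ids, la, lb = _paired_labels(records_a, records_b, condition)
    labels = sorted(set(la) | set(lb))
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for x, y in zip(la, lb):
        table.loc[x, y] += 1
    n = len(ids)
    po = float(np.trace(table.to_numpy())) / n
    marg_a = table.sum(axis=1).to_numpy() / n
    marg_b = table.sum(axis=0).to_numpy() / n
    pe = float(marg_a @ marg_b)
    if pe >= 1.0 - 1e-15:
        kappa = 1.0 if po >= 1.0 - 1e-15 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(kappa=kappa, po=po, pe=pe, n_items=n, contingency=table)


def agreement_gate(result: AgreementResult, threshold: float = 0.8) -> bool:
    """Pass iff kappa >= threshold (boundary inclusive)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return result.kappa >= threshold


def find_disagreements(
    records_a: Iterable[AnnotationRecord],
    records_b: Iterable[AnnotationRecord],
    condition: str,
) -> list[tuple[str, str, str]]:
    """The items on which the annotators differ, in annotator-A record order."""
    ids, la, lb = _paired_labels(records_a, records_b, condition)
    return [(i, x, y) for i, x, y in zip(ids, la, lb) if x != y]


def select_for_revision(
    sentences: Sequence[Sentence], plan: CorrectionPlan
) -> list[str]:
    """Sentences whose normalized text contains any ambiguous term.

    Case-insensitive substring containment; each sentence listed once, in
    input order.  The selection is recorded on the plan.
    """
    if not plan.ambiguous_terms:
        raise AnnotationError("correction plan has no ambiguous terms")
    terms = [normalized_key(t) for t in plan.ambiguous_terms]
    selected: list[str] = []
    for s in sentences:
        key = normalized_key(s.text)
        if any(t in key for t in terms):
            selected.append(s.sent_id)
    plan.selected_sent_ids = selected
    return selected


def apply_corrections(
    records: Sequence[AnnotationRecord],
    corrected: Mapping[str, str],
    guideline_version: str = "v2",
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Replace labels of selected sentences; archive the superseded records.

    Returns (updated records, archived originals).  The annotator id of a
    corrected record is suffixed with the guideline version as an audit tag.
    """
    updated: list[AnnotationRecord] = []
    archived: list[AnnotationRecord] = []
    for r in records:
        if r.sent_id in corrected and corrected[r.sent_id] != r.label:
            archived.append(r)
            updated.append(
                AnnotationRecord(
                    sent_id=r.sent_id,
                    annotator_id=f"{r.annotator_id}+{guideline_version}",
                    condition=r.condition,
                    label=corrected[r.sent_id],
                    duration_seconds=r.duration_seconds,
                )
            )
        else:
            updated.append(r)
    return updated, archived


def annotation_time_summary(
    records: Sequence[AnnotationRecord],
    gold_labels: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """Mean annotation seconds per sentence, overall and informative-only.

    Informative means the sentence's label (gold if provided, else the
    record's own) is not ``unknown``.  With no informative records the
    second mean is NaN (not applicable).
    """
    if not records:
        raise AnnotationError("no annotation records")
    durations = np.array([r.duration_seconds for r in records], dtype=float)
    if gold_labels is None:
        info = np.array([r.label != "unknown" for r in records])
    else:
        info = np.array(
            [gold_labels.get(r.sent_id, r.label) != "unknown" for r in records]
        )
    mean_all = float(durations.mean())
    mean_informative = float(durations[info].mean()) if info.any() else float("nan")
    return mean_all, mean_informative


# ---------------------------------------------------------------------------
# Serialization (JSON lines)
# ---------------------------------------------------------------------------

_FIELDS = ("sent_id", "annotator_id", "condition", "label", "duration_seconds")


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({f: getattr(r, f) for f in _FIELDS}, ensure_ascii=False) + "\n")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    out: list[AnnotationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out.append(AnnotationRecord(**{f: rec[f] for f in _FIELDS}))
            except (json.JSONDecodeError, KeyError) as exc:
                raise AnnotationError(f"line {lineno}: invalid annotation record ({exc})") from exc
    return out
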