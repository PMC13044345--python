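"""Document and sentence data model, segmentation, serialization, deduplication.

Clinical documents are plain text with provenance metadata (document id,
patient id, document type).  Sentences carry a character span into their
parent document so that every downstream label can be traced back to the
source text.  Segmentation is a deterministic rule splitter: a newline or a
terminal punctuation character (``. ! ?``) ends a sentence, unless the period
belongs to a protected abbreviation ("M.", "Dr.", ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "Sentence",
    "CorpusFormatError",
    "DOC_TYPES",
    "normalized_key",
    "segment_document",
    "segment_corpus",
    "deduplicate",
    "read_corpus",
    "write_corpus",
    "read_sentences",
    "write_sentences",
    "load_abbreviations",
    "default_abbreviations",
]

#: Controlled vocabulary of clinical document types (nine frequent categories
#: plus a catch-all).
DOC_TYPES = (
    "nursing_care_procedures",
    "medical_reports",
    "nursing_care_monitoring",
    "daily_notes",
    "imaging_reports",
    "prescriptions",
    "paramedical_care",
    "administrative",
    "pathology_reports",
    "Other",
)

_REQUIRED_DOC_FIELDS = ("doc_id", "patient_id", "doc_type", "text")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or invalid document content."""


@dataclass
class Document:
    """A clinical document: raw text plus provenance metadata.

    ``extra`` holds unknown fields found when reading a corpus file so that
    round-tripping preserves them.
    """

    doc_id: str
    patient_id: str
    text: str
    doc_type: str = "Other"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusFormatError(f"document {self.doc_id!r}: text must be non-empty")
        if not self.doc_type:
            self.doc_type = "Other"


@dataclass(frozen=True)
class Sentence:
    """A segmented sentence with provenance and a 0-based half-open span."""

    sent_id: str
    doc_id: str
    patient_id: str
    doc_type: str
    text: str
    span: tuple[int, int]


def normalized_key(text: str) -> str:
    """Duplicate-detection key: lowercase, collapse internal whitespace, strip."""
    return " ".join(text.lower().split())


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

_TERMINATORS = ".!?"


def _protected(text: str, i: int, abbreviations: Sequence[str]) -> bool:
    """True if the period at position ``i`` lies inside a protected token."""
    for abbr in abbreviations:
        la = len(abbr)
        lo = max(0, i - la + 1)
        for j in range(lo, i + 1):
            if text[j : j + la].lower() != abbr.lower():
                continue
            if j <= i < j + la and (j == 0 or not (text[j - 1].isalnum() or text[j - 1] == ".")):
                return True
    return False


def segment_document(
    doc: Document, abbreviations: Sequence[str] = ()
) -> list[Sentence]:
    """Split a document into sentences with exact character spans.

    A sentence ends at a newline or at one of ``. ! ?`` (the terminator is
    kept inside the sentence), except for periods inside a protected
    abbreviation.  Returned spans are whitespace-trimmed, non-overlapping,
    ordered, and jointly cover every non-whitespace character of the text.
    """
    if not doc.text:
        raise CorpusFormatError(f"document {doc.doc_id!r}: cannot segment empty text")
    abbrs = [a if a.endswith(".") else a + "." for a in abbreviations]
    text = doc.text
    raw: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch == "\n":
            raw.append((start, i))
            start = i + 1
        elif ch in _TERMINATORS:
            if ch == "." and _protected(text, i, abbrs):
                continue
            raw.append((start, i + 1))
            start = i + 1
    if start < len(text):
        raw.append((start, len(text)))

    sentences: list[Sentence] = []
    for lo, hi in raw:
        seg = text[lo:hi]
        stripped = seg.strip()
        if not stripped:
            continue
        a = lo + (len(seg) - len(seg.lstrip()))
        b = a + len(stripped)
        sentences.append(
            Sentence(
                sent_id=f"{doc.doc_id}:{a}",
                doc_id=doc.doc_id,
                patient_id=doc.patient_id,
                doc_type=doc.doc_type,
                text=stripped,
                span=(a, b),
            )
        )
    return sentences


def segment_corpus(
    docs: Iterable[Document], abbreviations: Sequence[str] = ()
) -> list[Sentence]:
    out: list[Sentence] = []
    for doc in docs:
        out.extend(segment_document(doc, abbreviations))
    return out


def deduplicate(sentences: Sequence[Sentence]) -> tuple[list[Sentence], int]:
    """Drop sentences whose normalized text was already seen; keep first.

    Returns the unique sentences (input order) and the number removed.
    """
    seen: set[str] = set()
    unique: list[Sentence] = []
    for s in sentences:
        key = normalized_key(s.text)
        if key in seen:
            continue
        seen.add(key)
        unique.append(s)
    return unique, len(sentences) - len(unique)


# ---------------------------------------------------------------------------
# Serialization (JSON lines)
# ---------------------------------------------------------------------------


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSON-lines corpus; one document per line.

    Unknown extra fields are preserved on the returned documents.  Errors
    name the offending line and field.
    """
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            for fname in _REQUIRED_DOC_FIELDS:
                if fname not in rec:
                    raise CorpusFormatError(f"line {lineno}: missing required field {fname!r}")
            extra = {k: v for k, v in rec.items() if k not in _REQUIRED_DOC_FIELDS}
            docs.append(
                Document(
                    doc_id=rec["doc_id"],
                    patient_id=rec["patient_id"],
                    doc_type=rec["doc_type"],
                    text=rec["text"],
                    extra=extra,
                )
            )
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CorpusFormatError(f"duplicate doc_id values: {dupes}")
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "patient_id": doc.patient_id,
                "doc_type": doc.doc_type,
                "text": doc.text,
                **doc.extra,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_sentences(sentences: Iterable[Sentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {
                "sent_id": s.sent_id,
                "doc_id": s.doc_id,
                "patient_id": s.patient_id,
                "doc_type": s.doc_type,
                "text": s.text,
                "span_start": s.span[0],
                "span_end": s.span[1],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_sentences(path: str | Path) -> list[Sentence]:
    out: list[Sentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            try:
                out.append(
                    Sentence(
                        sent_id=rec["sent_id"],
                        doc_id=rec["doc_id"],
                        patient_id=rec["patient_id"],
                        doc_type=rec["doc_type"],
                        text=rec["text"],
                        span=(rec["span_start"], rec["span_end"]),
                    )
                )
            except KeyError as exc:
                raise CorpusFormatError(f"line {lineno}: missing required field {exc.args[0]!r}") from exc
    return out


def load_abbreviations(path: str | Path) -> list[str]:
    """One protected token per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        tok = line.strip()
        if tok and not tok.startswith("#"):
            out.append(tok)
    return out


def default_abbreviations() -> list[str]:
    """Protected French clinical abbreviations shipped with the package."""
    return load_abbreviations(Path(__file__).parent / "data" / "abbreviations_fr.txt")
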