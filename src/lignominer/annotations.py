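"""Document and annotation data model with standoff serialization.

Annotations are typed, feature-bearing character spans over a document's
(ligature-normalized) text.  Fifteen entity types are recognised, split
between word-level mentions (enzyme, organism, gene, ... names) and
sentence-level biochemical contexts (pH, temperature, kinetics, ...).

Offsets are 0-based, half-open character indices into ``Document.text``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

__all__ = [
    "ENTITY_LEVELS",
    "ENTITY_TYPES",
    "FEATURE_KEYS",
    "Span",
    "Document",
    "Annotation",
    "AnnotationSet",
    "AnnotationError",
    "SchemaError",
    "StandoffParseError",
    "add_annotation",
    "read_standoff",
    "write_standoff",
    "write_brat",
]

#: Entity type -> applicable level: "W" (word/phrase mention) or "S" (whole sentence).
ENTITY_LEVELS: Dict[str, str] = {
    "ActivityAssayConditions": "S",
    "Assay": "W",
    "Enzyme": "W",
    "Gene": "W",
    "Glycosylation": "S",
    "Host": "W",
    "KineticAssayConditions": "S",
    "Organism": "W",
    "pH": "S",
    "ProductAnalysis": "S",
    "SpecificActivity": "S",
    "Strain": "W",
    "Substrate": "W",
    "SubstrateSpecificity": "S",
    "Temperature": "S",
}

ENTITY_TYPES = tuple(sorted(ENTITY_LEVELS))

#: Registry of allowed annotation feature keys.
FEATURE_KEYS = frozenset(
    {
        "normalized_value",
        "unit",
        "range_hi",
        "ec_number",
        "taxid",
        "recommended_name",
        "systematic_name",
        "swissprot_ids",
        "url",
        "antecedent_span",
        "antecedent_surface",
        "rule_id",
        "source",
        "ambiguous",
        "form",
        "normalized_name",
        "rank",
        "attached_organism",
        "optimum",
        "profile_pairs",
        "cues",
        "quantities",
        "implausible",
        "grounded",
        "note",
    }
)


class AnnotationError(ValueError):
    """Raised for invalid spans or other annotation-level violations."""


class SchemaError(AnnotationError):
    """Raised for unknown entity types or feature keys."""


class StandoffParseError(ValueError):
    """Raised when a standoff file is malformed or inconsistent."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Document:
    """A plain-text article with an opaque identifier."""

    doc_id: str
    text: str
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise AnnotationError("doc_id must be non-empty")


@dataclass
class Annotation:
    """A typed span on one document, with string-valued features."""

    etype: str
    span: Span
    surface: str
    features: Dict[str, str] = field(default_factory=dict)
    set_name: str = "system"

    def key(self) -> Tuple[int, int, str]:
        return (self.span.start, self.span.end, self.etype)


class AnnotationSet:
    """Ordered, duplicate-free collection of annotations on one document.

    Kept sorted by ``(start, end, etype)``; adding an exact duplicate
    ``(etype, span)`` is a no-op that returns the stored annotation.
    """

    def __init__(self, name: str, doc_id: str):
        self.name = name
        self.doc_id = doc_id
        self._anns: List[Annotation] = []
        self._index: Dict[Tuple[str, int, int], Annotation] = {}

    def add(self, ann: Annotation) -> Annotation:
        key = (ann.etype, ann.span.start, ann.span.end)
        existing = self._index.get(key)
        if existing is not None:
            return existing
        ann.set_name = self.name
        self._index[key] = ann
        self._anns.append(ann)
        self._anns.sort(key=Annotation.key)
        return ann

    def get(self, etype: str, span: Span) -> Optional[Annotation]:
        return self._index.get((etype, span.start, span.end))

    def by_type(self, etype: str) -> List[Annotation]:
        return [a for a in self._anns if a.etype == etype]

    def types(self) -> List[str]:
        return sorted({a.etype for a in self._anns})

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self._anns)

    def __len__(self) -> int:
        return len(self._anns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.name == other.name
            and self.doc_id == other.doc_id
            and [(a.etype, a.span, a.surface, a.features) for a in self]
            == [(a.etype, a.span, a.surface, a.features) for a in other]
        )


def add_annotation(
    doc: Document,
    aset: AnnotationSet,
    etype: str,
    span: Span,
    features: Optional[Mapping[str, str]] = None,
) -> Annotation:
    """Create and store an annotation, auto-filling its surface form.

    Duplicate ``(etype, span)`` pairs are merged: the existing annotation is
    returned unchanged.  Out-of-bounds spans raise :class:`AnnotationError`;
    unknown entity types or feature keys raise :class:`SchemaError`.
    """
    if etype not in ENTITY_LEVELS:
        raise SchemaError(f"unknown entity type {etype!r}")
    if span.end > len(doc.text):
        raise AnnotationError(
            f"span [{span.start}, {span.end}) exceeds text length {len(doc.text)}"
        )
    feats = dict(features or {})
    for k in feats:
        if k not in FEATURE_KEYS:
            raise SchemaError(f"unknown feature key {k!r}")
    ann = Annotation(etype=etype, span=span, surface=doc.text[span.start : span.end], features=feats)
    return aset.add(ann)


# ---------------------------------------------------------------------------
# Standoff JSON serialization
# ---------------------------------------------------------------------------
# Dialect: one JSON object per article:
#   {"doc_id": ..., "text": ..., "meta": {...},
#    "sets": {set_name: [{"type","start","end","surface","features"}, ...]}}
# Output is deterministic: sets and feature keys sorted, annotations in
# (start, end, type) order.


def write_standoff(doc: Document, sets: Mapping[str, AnnotationSet], path) -> None:
    """Serialize a document and its annotation sets to standoff JSON."""
    for name, aset in sets.items():
        if aset.doc_id != doc.doc_id:
            raise AnnotationError(
                f"set {name!r} belongs to document {aset.doc_id!r}, not {doc.doc_id!r}"
            )
    payload = {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "meta": dict(sorted(doc.meta.items())),
        "sets": {
            name: [
                {
                    "type": a.etype,
                    "start": a.span.start,
                    "end": a.span.end,
                    "surface": a.surface,
                    "features": dict(sorted(a.features.items())),
                }
                for a in sets[name]
            ]
            for name in sorted(sets)
        },
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )


def read_standoff(path) -> Tuple[Document, Dict[str, AnnotationSet]]:
    """Read a standoff JSON file; inverse of :func:`write_standoff`."""
    raw = Path(path).read_text(encoding="utf-8")
    try:
        payload = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise StandoffParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    try:
        doc = Document(payload["doc_id"], payload["text"], dict(payload.get("meta", {})))
        sets: Dict[str, AnnotationSet] = {}
        for name, records in payload.get("sets", {}).items():
            aset = AnnotationSet(name, doc.doc_id)
            for i, rec in enumerate(records):
                span = Span(int(rec["start"]), int(rec["end"]))
                surface = doc.text[span.start : span.end]
                if rec.get("surface", surface) != surface:
                    raise StandoffParseError(
                        f"{path}: set {name!r} record {i}: surface "
                        f"{rec['surface']!r} != text slice {surface!r}"
                    )
                ann = add_annotation(doc, aset, rec["type"], span, rec.get("features", {}))
                if ann.surface != surface:  # pragma: no cover - defensive
                    raise StandoffParseError(f"{path}: set {name!r} record {i}: surface drift")
            sets[name] = aset
        return doc, sets
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, StandoffParseError):
            raise
        raise StandoffParseError(f"{path}: malformed standoff record: {exc}") from exc


def write_brat(doc: Document, aset: AnnotationSet, path) -> None:
    """Export one annotation set as brat-style standoff (.ann).

    T-lines carry type and offsets; features are emitted as A-lines
    (``A<n>\\t<key> T<m> <value>``) for annotation-tool interoperability.
    """
    lines: List[str] = []
    a_counter = 1
    for t_counter, ann in enumerate(aset, start=1):
        surface = ann.surface.replace("\n", " ")
        lines.append(f"T{t_counter}\t{ann.etype} {ann.span.start} {ann.span.end}\t{surface}")
        for key in sorted(ann.features):
            value = ann.features[key].replace("\n", " ").replace("\t", " ")
            lines.append(f"A{a_counter}\t{key} T{t_counter} {value}")
            a_counter += 1
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
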