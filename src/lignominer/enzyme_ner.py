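"""Enzyme mention detection, abbreviation coreference and grounding.

Detection combines two sources: gazetteer matches against a BRENDA-style
enzyme lexicon, and a morphological rule that proposes word tokens ending in
"-ase"/"-ases" (minimum stem length 4, filtered through an editable stoplist
of common English false positives such as "disease" or "increase").
Gazetteer matches win over suffix candidates on overlap.

Authors routinely coin document-local abbreviations ("the extracellular
endoglucanase (EG) was purified ... The purified EG ..."); these never appear
in enzyme nomenclature resources, so a definition detector records
``<enzyme> (<short form>)`` patterns — validated by a Schwartz–Hearst-style
in-order letter-subsequence test — and a forward-only coreference pass
annotates later standalone occurrences of the short form, copying the
antecedent's grounding.

Grounding attaches Recommended Name, Systematic Name, EC number, SwissProt
identifiers and a resource URL from the lexicon entry; suffix-only candidates
absent from the lexicon stay ungrounded with provenance "suffix_rule".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .annotations import Annotation, AnnotationSet, Document, Span, add_annotation
from .lexicon import EnzymeLexiconEntry, Lexicon, match
from .preprocess import Token
from .resources import load_list

__all__ = [
    "AbbreviationRecord",
    "GroundedEnzyme",
    "load_ase_stoplist",
    "detect_suffix_candidates",
    "detect_enzymes",
    "detect_abbreviation_definitions",
    "resolve_abbreviations",
    "ground_enzyme",
    "abbreviation_miss_report",
]

logger = logging.getLogger(__name__)

MIN_STEM_LEN = 4
MAX_SHORT_FORM_LEN = 10


@dataclass(frozen=True)
class AbbreviationRecord:
    """A document-local short-form definition: ``long_form (short_form)``."""

    doc_id: str
    short_surface: str
    short_span: Span
    long_surface: str
    long_span: Span


@dataclass
class GroundedEnzyme:
    """Grounding result for one enzyme mention."""

    span: Span
    surface: str
    recommended_name: str = ""
    systematic_name: str = ""
    ec_number: str = ""
    swissprot_ids: Tuple[str, ...] = ()
    url: str = ""
    ambiguous: bool = False
    grounded: bool = False
    provenance: str = "gazetteer"


def load_ase_stoplist(path=None) -> frozenset:
    entries = load_list(path if path is not None else "lists/ase_stoplist.txt")
    return frozenset(e.casefold() for e in entries)


def detect_suffix_candidates(
    tokens: Sequence[Token], stoplist: frozenset
) -> List[Span]:
    """Word tokens ending in -ase/-ases with stem length >= 4, minus stoplist."""
    out: List[Span] = []
    for tok in tokens:
        if tok.kind != "word":
            continue
        low = tok.lower
        if low.endswith("ases"):
            stem = low[:-4]
        elif low.endswith("ase"):
            stem = low[:-3]
        else:
            continue
        if len(stem) < MIN_STEM_LEN:
            continue
        if low in stoplist or (low.endswith("s") and low[:-1] in stoplist):
            continue
        out.append(tok.span)
    return out


def detect_enzymes(
    doc: Document,
    tokens: Sequence[Token],
    enzyme_lexicon: Lexicon,
    stoplist: Optional[frozenset] = None,
    aset: Optional[AnnotationSet] = None,
) -> List[Annotation]:
    """Union of gazetteer matches and suffix candidates (gazetteer wins overlaps)."""
    if stoplist is None:
        stoplist = load_ase_stoplist()
    if aset is None:
        aset = AnnotationSet("system", doc.doc_id)
    anns: List[Annotation] = []
    gaz_spans: List[Span] = []
    for span, entries in match(tokens, enzyme_lexicon):
        feats = {"source": "gazetteer"}
        anns.append(add_annotation(doc, aset, "Enzyme", span, feats))
        gaz_spans.append(span)
    for span in detect_suffix_candidates(tokens, stoplist):
        if any(span.overlaps(g) for g in gaz_spans):
            continue
        anns.append(
            add_annotation(doc, aset, "Enzyme", span, {"source": "suffix_rule", "rule_id": "ase_suffix"})
        )
    return anns


def _letters(s: str) -> str:
    return "".join(c for c in s.casefold() if c.isalpha())


def _is_subsequence(short: str, long: str) -> bool:
    it = iter(long)
    return all(c in it for c in short)


def detect_abbreviation_definitions(
    doc: Document,
    tokens: Sequence[Token],
    enzyme_annotations: Sequence[Annotation],
) -> List[AbbreviationRecord]:
    """Record ``<enzyme mention> ( <short form> )`` definitions.

    The short form must be a single token of 1-10 characters containing no
    digits, immediately parenthesised after the mention, whose letters occur
    in order within the long form (rejects figure/table references like
    "(Fig. 2)" both by the digit rule and by the subsequence test).
    """
    records: List[AbbreviationRecord] = []
    starts = {t.span.start: i for i, t in enumerate(tokens)}
    by_end: Dict[int, int] = {t.span.end: i for i, t in enumerate(tokens)}
    for ann in sorted(enzyme_annotations, key=lambda a: a.span.start):
        i = by_end.get(ann.span.end)
        if i is None or i + 2 >= len(tokens):
            continue
        if tokens[i + 1].surface != "(":
            continue
        short_tok = tokens[i + 2]
        if i + 3 >= len(tokens) or tokens[i + 3].surface != ")":
            continue
        short = short_tok.surface
        if short_tok.kind != "word" or not (1 <= len(short) <= MAX_SHORT_FORM_LEN):
            continue
        if any(c.isdigit() for c in short):
            continue
        if len(short) >= len(ann.surface):
            continue
        if not _is_subsequence(_letters(short), _letters(ann.surface)):
            continue
        records.append(
            AbbreviationRecord(
                doc_id=doc.doc_id,
                short_surface=short,
                short_span=short_tok.span,
                long_surface=ann.surface,
                long_span=ann.span,
            )
        )
    return records


def resolve_abbreviations(
    doc: Document,
    tokens: Sequence[Token],
    records: Sequence[AbbreviationRecord],
    aset: AnnotationSet,
) -> List[Annotation]:
    """Annotate later standalone occurrences of defined short forms.

    Scope is forward-only from the defining occurrence; if one short form is
    redefined, the later definition shadows the earlier one from its position
    onward.  New annotations copy the antecedent's grounding features and
    record the antecedent span.
    """
    by_short: Dict[str, List[AbbreviationRecord]] = {}
    for rec in sorted(records, key=lambda r: r.short_span.start):
        by_short.setdefault(rec.short_surface, []).append(rec)
    for short, recs in by_short.items():
        if len(recs) > 1:
            logger.info(
                "%s: short form %r redefined %d times; later definitions shadow earlier",
                doc.doc_id, short, len(recs),
            )
    existing = sorted((a.span for a in aset.by_type("Enzyme")), key=lambda s: s.start)
    antecedents = {
        (a.span.start, a.span.end): a for a in aset.by_type("Enzyme")
    }
    new_anns: List[Annotation] = []
    for tok in tokens:
        if tok.kind != "word":
            continue
        recs = by_short.get(tok.surface)
        if not recs:
            continue
        # latest definition occurring strictly before this token
        rec = None
        for r in recs:
            if r.short_span.end <= tok.span.start:
                rec = r
        if rec is None:
            continue
        if any(tok.span.overlaps(s) for s in existing):
            continue
        ante = antecedents.get((rec.long_span.start, rec.long_span.end))
        feats = {}
        if ante is not None:
            feats = {
                k: v
                for k, v in ante.features.items()
                if k in {
                    "ec_number", "recommended_name", "systematic_name",
                    "swissprot_ids", "url", "ambiguous", "grounded",
                }
            }
        feats["source"] = "abbreviation"
        feats["antecedent_span"] = f"{rec.long_span.start}:{rec.long_span.end}"
        feats["antecedent_surface"] = rec.long_surface
        ann = add_annotation(doc, aset, "Enzyme", tok.span, feats)
        existing.append(tok.span)
        new_anns.append(ann)
    return new_anns


def ground_enzyme(annotation: Annotation, enzyme_lexicon: Lexicon) -> GroundedEnzyme:
    """Ground one Enzyme annotation against the lexicon, updating its features.

    Lookup uses the mention surface (or the antecedent surface for
    abbreviation-derived mentions); a terminal plural "s" is stripped on a
    failed lookup.  Multiple entries with distinct EC numbers set the
    ambiguous flag and list every EC.
    """
    surface = annotation.features.get("antecedent_surface", annotation.surface)
    entries = enzyme_lexicon.lookup_surface(surface)
    if not entries and surface.endswith("s"):
        entries = enzyme_lexicon.lookup_surface(surface[:-1])
    entries = [e for e in entries if isinstance(e, EnzymeLexiconEntry)]
    result = GroundedEnzyme(
        span=annotation.span,
        surface=annotation.surface,
        provenance=annotation.features.get("source", "gazetteer"),
    )
    if not entries:
        annotation.features.setdefault("source", "suffix_rule")
        annotation.features["grounded"] = "false"
        return result
    ecs = sorted({e.ec_number for e in entries})
    first = entries[0]
    result.recommended_name = first.recommended_name
    result.systematic_name = first.systematic_name
    result.ec_number = "|".join(ecs)
    result.swissprot_ids = tuple(
        pid for e in entries for pid in e.swissprot_ids
    )
    result.url = first.url
    result.ambiguous = len(ecs) > 1
    result.grounded = True
    annotation.features.update(
        {
            "recommended_name": result.recommended_name,
            "ec_number": result.ec_number,
            "url": result.url,
            "grounded": "true",
        }
    )
    if result.systematic_name:
        annotation.features["systematic_name"] = result.systematic_name
    if result.swissprot_ids:
        annotation.features["swissprot_ids"] = "|".join(result.swissprot_ids)
    if result.ambiguous:
        annotation.features["ambiguous"] = "true"
    return result


def abbreviation_miss_report(
    gold: AnnotationSet, system: AnnotationSet
) -> Dict[str, object]:
    """Audit hook: fraction of gold Enzyme false negatives that look like
    author abbreviations (short, spaceless, containing uppercase letters).

    Returns counts and the abbreviation-attributable fraction so that corpus
    runs can report how much recall is lost to abbreviation handling.
    """
    sys_spans = {(a.span.start, a.span.end) for a in system.by_type("Enzyme")}
    misses = [
        a for a in gold.by_type("Enzyme")
        if (a.span.start, a.span.end) not in sys_spans
    ]
    abbrev_like = [
        a for a in misses
        if len(a.surface) <= MAX_SHORT_FORM_LEN
        and " " not in a.surface
        and any(c.isupper() for c in a.surface)
    ]
    n_miss = len(misses)
    return {
        "false_negatives": n_miss,
        "abbreviation_like": len(abbrev_like),
        "fraction": (len(abbrev_like) / n_miss) if n_miss else 0.0,
    }
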