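"""Sentence-level context detection and biochemical quantity normalization.

Enzyme characterization prose reports catalytic properties as numbers with
units inside stereotyped sentences: temperature optima and stability
("maximum activity at 55°C, with 84% relative activity at 60°C"), pH profiles
("optimum activity at pH 5.0"), specific activities ("43.33 U/mg protein"),
kinetic and activity assay conditions, substrate specificity, glycosylation
state and reaction-product analyses.

This module extracts and normalizes those quantities (°C, pH, U/mg, %, molar
concentrations, including "between pH 2.0 and 7.0" ranges and space-grouped
thousands like "27 000"), classifies sentences into the eight sentence-level
entity types using editable cue vocabularies, pulls out the optimum value
when an optimum cue governs it, and pairs relative-activity percentages with
the condition values they describe (a single percentage distributes over
"and also at" coordination).

Word-level Assay and Substrate mentions come from gazetteers; Gene mentions
from a shape rule ("mel36F") anchored to the cues "gene"/"encoding".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotations import Annotation, AnnotationSet, Document, Span, add_annotation
from .lexicon import Lexicon, match
from .preprocess import SentenceSpan, Token
from .resources import load_list

__all__ = [
    "QuantityMention",
    "ContextSentence",
    "CueLexicons",
    "extract_quantities",
    "classify_sentences",
    "extract_optimum",
    "extract_profile_pairs",
    "detect_word_level_misc",
]

logger = logging.getLogger(__name__)

_NUM = r"\d{1,3}(?:[ \u00A0]\d{3})+(?!\d)|\d+\.\d+|\d+"


def _to_float(num: str) -> float:
    return float(num.replace("\u00A0", "").replace(" ", ""))


@dataclass
class QuantityMention:
    """A normalized numeric value with unit (optionally a range)."""

    kind: str  # temperature_C | pH | specific_activity_U_per_mg | relative_activity_pct | molar_conc
    value: float
    span: Span
    unit_surface: str
    text_value: str  # numeral exactly as printed, for canonical string features
    range_hi: Optional[float] = None
    range_hi_text: Optional[str] = None
    flagged: bool = False  # e.g. pH outside [0, 14]


@dataclass
class ContextSentence:
    """One sentence carrying a sentence-level entity type."""

    span: Span
    etype: str
    quantities: List[QuantityMention] = field(default_factory=list)
    cues: List[str] = field(default_factory=list)
    optimum: Optional[QuantityMention] = None


# Patterns are applied in priority order on the sentence text; a number
# consumed by an earlier pattern is masked from later ones.
_PH_RE = re.compile(
    rf"\bpH\s*(?P<v>{_NUM})(?:\s+(?:and|to)\s+(?P<hi>{_NUM})(?!\s*(?:%|°|U\b)))?",
)
_TEMP_RE = re.compile(rf"(?P<v>{_NUM})\s*°\s*C\b")
_SPEC_RE = re.compile(rf"(?P<v>{_NUM})\s*U\s*/\s*mg\b")
_PCT_RE = re.compile(rf"(?P<v>{_NUM})\s*%")
_MOLAR_RE = re.compile(rf"(?P<v>{_NUM})\s*(?P<u>mM|M)(?![A-Za-z])")


def extract_quantities(sentence_text: str, sentence_span: Span) -> List[QuantityMention]:
    """Extract normalized quantities from one sentence.

    Spans are absolute (offset by the sentence start).  "pH N and M" /
    "between pH N and M" produce a range when M > N, otherwise two separate
    mentions.
    """
    offset = sentence_span.start
    out: List[QuantityMention] = []
    consumed: List[Tuple[int, int]] = []

    def is_free(a: int, b: int) -> bool:
        return not any(a < c2 and c1 < b for c1, c2 in consumed)

    for m in _PH_RE.finditer(sentence_text):
        if not is_free(m.start(), m.end()):
            continue
        v = _to_float(m.group("v"))
        hi_txt = m.group("hi")
        lo_flag = not (0.0 <= v <= 14.0)
        if hi_txt is not None:
            hi = _to_float(hi_txt)
            if hi > v:
                out.append(
                    QuantityMention(
                        "pH", v, Span(offset + m.start(), offset + m.end()), "pH",
                        m.group("v"), range_hi=hi, range_hi_text=hi_txt, flagged=lo_flag,
                    )
                )
                consumed.append((m.start(), m.end()))
                continue
            # descending "range" -> two independent mentions
            out.append(
                QuantityMention(
                    "pH", v,
                    Span(offset + m.start(), offset + m.start("v") + len(m.group("v"))),
                    "pH", m.group("v"), flagged=lo_flag,
                )
            )
            out.append(
                QuantityMention(
                    "pH", hi,
                    Span(offset + m.start("hi"), offset + m.end("hi")),
                    "pH", hi_txt, flagged=not (0.0 <= hi <= 14.0),
                )
            )
            consumed.append((m.start(), m.end()))
            continue
        out.append(
            QuantityMention(
                "pH", v, Span(offset + m.start(), offset + m.end()), "pH",
                m.group("v"), flagged=lo_flag,
            )
        )
        consumed.append((m.start(), m.end()))

    for regex, kind, unit in (
        (_TEMP_RE, "temperature_C", "°C"),
        (_SPEC_RE, "specific_activity_U_per_mg", "U/mg"),
        (_PCT_RE, "relative_activity_pct", "%"),
    ):
        for m in regex.finditer(sentence_text):
            if not is_free(m.start(), m.end()):
                continue
            out.append(
                QuantityMention(
                    kind, _to_float(m.group("v")),
                    Span(offset + m.start(), offset + m.end()), unit, m.group("v"),
                )
            )
            consumed.append((m.start(), m.end()))

    for m in _MOLAR_RE.finditer(sentence_text):
        if not is_free(m.start(), m.end()):
            continue
        out.append(
            QuantityMention(
                "molar_conc", _to_float(m.group("v")),
                Span(offset + m.start(), offset + m.end()), m.group("u"), m.group("v"),
            )
        )
        consumed.append((m.start(), m.end()))

    out.sort(key=lambda q: q.span.start)
    return out


_CUE_FILES = {
    "activity_stability": "cues/activity_stability.txt",
    "kinetic": "cues/kinetic.txt",
    "assay_conditions": "cues/assay_conditions.txt",
    "glycosylation": "cues/glycosylation.txt",
    "specificity": "cues/specificity.txt",
    "product": "cues/product.txt",
}


class CueLexicons:
    """Cue vocabularies for sentence classification.

    Entries ending in ``*`` match as prefixes of a word (morpheme cues such
    as ``glycosyl*``); all others match at word boundaries, case-insensitive,
    and may be multi-word phrases.
    """

    def __init__(self, paths: Optional[Dict[str, str]] = None):
        paths = paths or {}
        self._regexes: Dict[str, List[Tuple[str, re.Pattern]]] = {}
        for name, default in _CUE_FILES.items():
            entries = load_list(paths.get(name, default))
            compiled = []
            for cue in entries:
                if cue.endswith("*"):
                    pat = re.compile(r"\b" + re.escape(cue[:-1].casefold()))
                else:
                    pat = re.compile(r"\b" + re.escape(cue.casefold()) + r"\b")
                compiled.append((cue, pat))
            self._regexes[name] = compiled

    def hits(self, name: str, text_low: str) -> List[str]:
        return [cue for cue, pat in self._regexes[name] if pat.search(text_low)]


def classify_sentences(
    doc: Document,
    sentences: Sequence[SentenceSpan],
    quantities_by_sentence: Sequence[List[QuantityMention]],
    cue_lexicons: CueLexicons,
    word_annotations: Sequence[Annotation] = (),
) -> List[ContextSentence]:
    """Assign sentence-level entity types; a sentence may bear several."""
    contexts: List[ContextSentence] = []
    for sent, quants in zip(sentences, quantities_by_sentence):
        text_low = doc.text[sent.span.start : sent.span.end].casefold()
        kinds = {q.kind for q in quants}
        in_sent = [
            a for a in word_annotations
            if sent.span.start <= a.span.start and a.span.end <= sent.span.end
        ]
        act_cues = cue_lexicons.hits("activity_stability", text_low)

        def emit(etype: str, cues: List[str]) -> None:
            contexts.append(
                ContextSentence(span=sent.span, etype=etype, quantities=list(quants), cues=cues)
            )

        if "temperature_C" in kinds and act_cues:
            emit("Temperature", act_cues)
        if "pH" in kinds and act_cues:
            emit("pH", act_cues)
        if "specific_activity_U_per_mg" in kinds:
            emit("SpecificActivity", act_cues)
        kin_cues = cue_lexicons.hits("kinetic", text_low)
        if kin_cues and kinds & {"molar_conc", "pH", "temperature_C"}:
            emit("KineticAssayConditions", kin_cues)
        assay_cues = cue_lexicons.hits("assay_conditions", text_low)
        if assay_cues and kinds & {"molar_conc", "pH", "temperature_C"}:
            emit("ActivityAssayConditions", assay_cues)
        gly_cues = cue_lexicons.hits("glycosylation", text_low)
        if gly_cues:
            emit("Glycosylation", gly_cues)
        spec_cues = cue_lexicons.hits("specificity", text_low)
        if spec_cues and any(a.etype in ("Substrate", "Enzyme") for a in in_sent):
            emit("SubstrateSpecificity", spec_cues)
        prod_cues = cue_lexicons.hits("product", text_low)
        if prod_cues:
            emit("ProductAnalysis", prod_cues)
    return contexts


_OPTIMUM_RE = re.compile(
    r"(?:optimum|optimal|maximum|maximal)(?:\s+[\w-]+){0,3}?\s+(?:at|of|was|around|near)\b"
    r"|(?:temperature|ph)\s+optimum\s+(?:at|of|was)\b",
    re.IGNORECASE,
)

_KIND_FOR_ETYPE = {"Temperature": "temperature_C", "pH": "pH"}


def extract_optimum(context: ContextSentence, doc: Document) -> ContextSentence:
    """Store the quantity governed by an optimum cue, if any.

    The optimum is the first quantity of the context's kind whose mention
    starts after an optimum-cue match within the sentence; stability-only
    sentences have no optimum.
    """
    kind = _KIND_FOR_ETYPE.get(context.etype)
    if kind is None:
        return context
    text = doc.text[context.span.start : context.span.end]
    for m in _OPTIMUM_RE.finditer(text):
        cue_end = context.span.start + m.end()
        following = [
            q for q in context.quantities if q.kind == kind and q.span.start >= cue_end
        ]
        if following:
            context.optimum = following[0]
            return context
    return context


_COORD_RE = re.compile(r"\s*(?:,\s*)?(?:and|or)\s+(?:also\s+)?(?:at\s+)?\s*$")


def extract_profile_pairs(
    context: ContextSentence, doc: Document
) -> List[Tuple[float, float]]:
    """Pair relative-activity percentages with their condition values.

    Each percentage is paired with the nearest following condition quantity
    (temperature or pH, matching the context type) before the next
    percentage; when two conditions are coordinated ("at pH 3.0 and also at
    pH 8.0"), the single percentage distributes over both.  Returns
    ``(condition_value, relative_activity_pct)`` pairs; unpaired percentages
    are logged and omitted.
    """
    kind = _KIND_FOR_ETYPE.get(context.etype)
    if kind is None:
        return []
    pcts = [q for q in context.quantities if q.kind == "relative_activity_pct"]
    conds = [q for q in context.quantities if q.kind == kind]
    pairs: List[Tuple[float, float]] = []
    for idx, pct in enumerate(pcts):
        limit = pcts[idx + 1].span.start if idx + 1 < len(pcts) else context.span.end
        window = [q for q in conds if pct.span.end <= q.span.start < limit]
        if not window:
            logger.info("unpaired percentage %s%% in %r", pct.text_value, context.etype)
            continue
        pairs.append((window[0].value, pct.value))
        prev = window[0]
        for q in window[1:]:
            between = doc.text[prev.span.end : q.span.start]
            if _COORD_RE.fullmatch(between) or re.fullmatch(
                r"\s*(?:,\s*)?and\s+(?:also\s+)?(?:at\s+)?", between
            ):
                pairs.append((q.value, pct.value))
                prev = q
            else:
                break
    return pairs


_GENE_CUES = frozenset({"gene", "genes", "encoding", "encodes", "encoded"})
_GENE_SHAPE_RE = re.compile(r"^[a-z][A-Za-z0-9]{2,7}$")


def detect_word_level_misc(
    doc: Document,
    tokens: Sequence[Token],
    substrate_lexicon: Lexicon,
    assay_lexicon: Lexicon,
    aset: Optional[AnnotationSet] = None,
    exclude_spans: Sequence[Span] = (),
) -> List[Annotation]:
    """Detect Assay, Substrate (gazetteers) and Gene (shape rule + cue).

    ``exclude_spans`` suppresses gazetteer hits nested inside already-claimed
    mentions (a substrate word inside a multi-token enzyme name is part of
    the enzyme name, not a substrate mention).
    """
    if aset is None:
        aset = AnnotationSet("system", doc.doc_id)
    anns: List[Annotation] = []
    for span, entries in match(tokens, substrate_lexicon):
        if any(span.overlaps(x) for x in exclude_spans):
            continue
        anns.append(add_annotation(doc, aset, "Substrate", span, {"source": "gazetteer"}))
    for span, entries in match(tokens, assay_lexicon):
        if any(span.overlaps(x) for x in exclude_spans):
            continue
        anns.append(add_annotation(doc, aset, "Assay", span, {"source": "gazetteer"}))
    words = [t for t in tokens if t.kind in ("word", "number")]
    for j, tok in enumerate(words):
        if tok.kind != "word" or not _GENE_SHAPE_RE.match(tok.surface):
            continue
        if not any(c.isdigit() for c in tok.surface):
            continue
        neighborhood = words[max(0, j - 2) : j + 3]
        if any(w.lower in _GENE_CUES for w in neighborhood if w is not tok):
            anns.append(
                add_annotation(doc, aset, "Gene", tok.span, {"source": "shape_rule", "rule_id": "gene_cue"})
            )
    return anns


def context_annotations(
    doc: Document,
    contexts: Sequence[ContextSentence],
    aset: AnnotationSet,
) -> List[Annotation]:
    """Materialise ContextSentences as sentence-level annotations."""
    anns: List[Annotation] = []
    for ctx in contexts:
        feats: Dict[str, str] = {"cues": "|".join(ctx.cues)}
        if ctx.quantities:
            feats["quantities"] = ";".join(
                f"{q.kind}={q.text_value}" + (f"-{q.range_hi_text}" if q.range_hi is not None else "")
                for q in ctx.quantities
            )
        if ctx.optimum is not None:
            feats["optimum"] = ctx.optimum.text_value
            feats["unit"] = ctx.optimum.unit_surface
        if ctx.etype in ("Temperature", "pH"):
            pairs = extract_profile_pairs(ctx, doc)
            if pairs:
                feats["profile_pairs"] = ";".join(
                    f"{c:g}:{p:g}" for c, p in pairs
                )
        if ctx.etype == "SpecificActivity":
            sa = [q for q in ctx.quantities if q.kind == "specific_activity_U_per_mg"]
            if sa:
                feats["normalized_value"] = sa[0].text_value
                feats["unit"] = "U/mg"
        if any(q.flagged for q in ctx.quantities):
            feats["implausible"] = "true"
        anns.append(add_annotation(doc, aset, ctx.etype, ctx.span, feats))
    return anns
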