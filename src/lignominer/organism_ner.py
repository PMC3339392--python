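"""Rule-based organism, strain and expression-host detection.

Organism mentions are found four ways: taxonomy-lexicon hits, the binomial
grammar (known genus + lowercase species epithet), abbreviated binomials
("T. reesei", expanded from the nearest preceding genus sharing the initial),
and "Genus sp." / "Genus spp." constructions.  Generic group mentions
("cellulolytic fungi") are covered by a small cue list behind a config flag
(default on).  Fixed phrases that merely contain organism words ("bovine
serum albumin") are suppressed via an editable blocklist.

Every mention is normalized to a scientific name (binomial or genus) and,
when the name is present in the taxonomy lexicon, grounded to its taxid and
resource URL; spelling variants absent from the lexicon stay ungrounded and
flagged, which mirrors how curated taxonomies behave on misspellings.

Strains are alphanumeric designators ("F75", "ATCC 26921") immediately
following an organism mention or the cue words "strain"/"isolate".  Hosts are
organism mentions governed by an expression cue ("expressed in", "produced
in", "host", ...) in the same sentence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .annotations import Annotation, AnnotationSet, Document, Span, add_annotation
from .lexicon import Lexicon, TaxonLexiconEntry, match
from .preprocess import SentenceSpan, Token
from .resources import load_list

__all__ = [
    "OrganismMention",
    "StrainMention",
    "detect_organisms",
    "ground_organism",
    "detect_strains",
    "detect_hosts",
]

logger = logging.getLogger(__name__)

#: lowercase tokens that may follow a capitalized genus without being a species epithet
_NOT_EPITHETS = frozenset(
    "sp spp species strain strains isolate isolates cells culture cultures genus "
    "cellulase cellulases enzyme enzymes gene genes protein proteins "
    # function words and frequent verbs that never serve as epithets
    "were was have has been being with from that this these those which also "
    "when then than their there where while after before into onto upon over "
    "under during between among produced secreted grown grew showed show "
    "exhibited displayed contains contained expressed cultures isolated".split()
)

_STRAIN_TOKEN_RE = re.compile(r"^[A-Z][A-Za-z]*-?\d+[A-Za-z0-9-]*$")
_STRAIN_PREFIX_RE = re.compile(r"^[A-Z]{2,6}$")  # culture-collection prefix (ATCC, NRRL...)


@dataclass
class OrganismMention:
    span: Span
    surface: str
    normalized_name: str
    form: str  # full | abbreviated | genus_sp | genus | common
    taxid: Optional[int] = None
    url: str = ""
    rank: str = ""
    resolved: bool = True


@dataclass
class StrainMention:
    span: Span
    surface: str
    attached_organism: Optional[Span] = None


def _load_cues(path, default_name):
    return [c.casefold() for c in load_list(path if path is not None else default_name)]


def detect_organisms(
    doc: Document,
    tokens: Sequence[Token],
    taxon_lexicon: Lexicon,
    aset: Optional[AnnotationSet] = None,
    generic_mentions: bool = True,
    blocklist: Optional[Sequence[str]] = None,
    generic_cues: Optional[Sequence[str]] = None,
) -> List[Annotation]:
    """Detect organism mentions and record normalization features."""
    if aset is None:
        aset = AnnotationSet("system", doc.doc_id)
    if blocklist is None:
        blocklist = load_list("lists/organism_blocklist.txt")
    blocked = _blocked_intervals(doc.text, blocklist)
    genus_vocab = taxon_lexicon.genus_names()
    mentions: List[OrganismMention] = []

    # (a) lexicon hits (longest match)
    for span, entries in match(tokens, taxon_lexicon):
        entry = entries[0]
        if not isinstance(entry, TaxonLexiconEntry):
            continue
        surface = doc.text[span.start : span.end]
        parts = entry.scientific_name.split()
        form = "full" if len(parts) >= 2 else ("genus" if surface[0].isupper() else "common")
        if surface.casefold() != entry.scientific_name.casefold():
            form = "common"
        mentions.append(
            OrganismMention(span, surface, entry.scientific_name, form)
        )

    taken = [m.span for m in mentions]

    def free(span: Span) -> bool:
        return not any(span.overlaps(t) for t in taken)

    # (b,c,d) grammar rules over token pairs/triples
    last_genus_by_initial: Dict[str, str] = {}
    for m in sorted(mentions, key=lambda m: m.span.start):
        genus = m.normalized_name.split()[0]
        last_genus_by_initial[genus[0].upper()] = genus

    i = 0
    n = len(tokens)
    grammar: List[OrganismMention] = []
    while i < n:
        tok = tokens[i]
        if tok.kind == "word" and tok.surface[0].isupper() and tok.lower in genus_vocab:
            nxt = tokens[i + 1] if i + 1 < n else None
            # (d) "Genus sp." / "Genus spp." — supersedes a bare-genus lexicon hit
            if nxt is not None and nxt.kind == "word" and nxt.lower in ("sp", "spp"):
                end = nxt.span.end
                j = i + 2
                if j < n and tokens[j].surface == "." and tokens[j].span.start == end:
                    end = tokens[j].span.end
                span = Span(tok.span.start, end)
                contained = [m for m in mentions if span.contains(m.span)]
                if free(span) or contained:
                    for m in contained:
                        mentions.remove(m)
                        taken.remove(m.span)
                    if free(span):
                        grammar.append(
                            OrganismMention(
                                span, doc.text[span.start : span.end], tok.surface, "genus_sp"
                            )
                        )
                i += 2
                continue
            # (b) binomial: known genus + lowercase species epithet; a longer
            # binomial supersedes a bare-genus lexicon hit on its first token
            if (
                nxt is not None
                and nxt.kind == "word"
                and nxt.surface.islower()
                and nxt.surface.isalpha()
                and len(nxt.surface) >= 4
                and nxt.lower not in _NOT_EPITHETS
            ):
                span = Span(tok.span.start, nxt.span.end)
                contained = [
                    m for m in mentions
                    if span.contains(m.span) and len(m.span) < len(span)
                ]
                for m in contained:
                    mentions.remove(m)
                    taken.remove(m.span)
                if free(span):
                    name = f"{tok.surface} {nxt.surface}"
                    grammar.append(OrganismMention(span, name, name, "full"))
                    last_genus_by_initial[tok.surface[0].upper()] = tok.surface
                i += 2
                continue
        # (c) abbreviated binomial: "T. reesei"
        if (
            tok.kind == "word"
            and len(tok.surface) == 1
            and tok.surface.isupper()
            and i + 2 < n
            and tokens[i + 1].surface == "."
            and tokens[i + 1].span.start == tok.span.end
            and tokens[i + 2].kind == "word"
            and tokens[i + 2].surface.islower()
            and tokens[i + 2].surface.isalpha()
            and len(tokens[i + 2].surface) >= 4
            and tokens[i + 2].lower not in _NOT_EPITHETS
        ):
            span = Span(tok.span.start, tokens[i + 2].span.end)
            if free(span):
                genus = last_genus_by_initial.get(tok.surface)
                if genus:
                    name = f"{genus} {tokens[i + 2].surface}"
                    m = OrganismMention(span, doc.text[span.start : span.end], name, "abbreviated")
                else:
                    m = OrganismMention(
                        span, doc.text[span.start : span.end],
                        doc.text[span.start : span.end], "abbreviated", resolved=False,
                    )
                grammar.append(m)
            i += 3
            continue
        i += 1

    mentions.extend(grammar)
    taken = [m.span for m in mentions]

    # generic group mentions: "<adjective> fungi/yeast/bacteria"
    if generic_mentions:
        cues = set(_load_cues(None, "lists/generic_organism_cues.txt")
                   if generic_cues is None else [c.casefold() for c in generic_cues])
        for j in range(1, n):
            tok = tokens[j]
            prev = tokens[j - 1]
            if (
                tok.kind == "word"
                and tok.lower in cues
                and prev.kind == "word"
                and prev.surface.islower()
                and prev.surface.isalpha()
                and len(prev.surface) >= 5
                and prev.lower not in cues
            ):
                span = Span(prev.span.start, tok.span.end)
                if free(span):
                    mentions.append(
                        OrganismMention(
                            span, doc.text[span.start : span.end],
                            doc.text[span.start : span.end], "common",
                        )
                    )
                    taken.append(span)

    anns: List[Annotation] = []
    for m in sorted(mentions, key=lambda m: m.span.start):
        if any(m.span.start >= b[0] and m.span.end <= b[1] for b in blocked):
            continue
        m = ground_organism(m, taxon_lexicon)
        feats = {
            "normalized_name": m.normalized_name,
            "form": m.form,
            "grounded": "true" if m.taxid is not None else "false",
        }
        if m.taxid is not None:
            feats["taxid"] = str(m.taxid)
            if m.url:
                feats["url"] = m.url
            if m.rank:
                feats["rank"] = m.rank
        if not m.resolved:
            feats["note"] = "unresolved_abbreviation"
        anns.append(add_annotation(doc, aset, "Organism", m.span, feats))
    return anns


def _blocked_intervals(text: str, blocklist: Sequence[str]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    low = text.casefold()
    for phrase in blocklist:
        p = phrase.casefold()
        start = 0
        while True:
            k = low.find(p, start)
            if k < 0:
                break
            out.append((k, k + len(p)))
            start = k + 1
    return out


def ground_organism(mention: OrganismMention, taxon_lexicon: Lexicon) -> OrganismMention:
    """Attach taxid/URL by looking up the normalized name; misses stay flagged."""
    entries = [
        e
        for e in taxon_lexicon.lookup_surface(mention.normalized_name)
        if isinstance(e, TaxonLexiconEntry)
    ]
    if entries:
        e = entries[0]
        mention.taxid = e.taxid
        mention.url = e.url
        mention.rank = e.rank
        mention.normalized_name = e.scientific_name
    return mention


_STRAIN_CUES = frozenset({"strain", "strains", "isolate", "isolates"})


def detect_strains(
    doc: Document,
    tokens: Sequence[Token],
    organism_annotations: Sequence[Annotation],
    aset: Optional[AnnotationSet] = None,
) -> List[Annotation]:
    """Alphanumeric designators after an organism mention or a strain cue."""
    if aset is None:
        aset = AnnotationSet("system", doc.doc_id)
    org_ends = {a.span.end: a for a in organism_annotations}
    org_spans = sorted(organism_annotations, key=lambda a: a.span.start)
    anns: List[Annotation] = []
    n = len(tokens)
    for i, tok in enumerate(tokens):
        if tok.kind not in ("word", "number"):
            continue
        licensed = False
        if i > 0 and tokens[i - 1].lower in _STRAIN_CUES:
            licensed = True
        else:
            gap = doc.text[: tok.span.start]
            for end, _ in org_ends.items():
                if end <= tok.span.start and gap[end:].strip() == "":
                    licensed = True
                    break
        if not licensed:
            continue
        span = None
        if tok.kind == "word" and _STRAIN_TOKEN_RE.match(tok.surface):
            span = tok.span
        elif tok.kind == "word" and _STRAIN_PREFIX_RE.match(tok.surface):
            if i + 1 < n and tokens[i + 1].kind == "number":
                span = Span(tok.span.start, tokens[i + 1].span.end)
        if span is None:
            continue
        attached = None
        for org in org_spans:
            if org.span.end <= span.start:
                attached = org
        feats = {}
        if attached is not None:
            feats["attached_organism"] = f"{attached.span.start}:{attached.span.end}"
        anns.append(add_annotation(doc, aset, "Strain", span, feats))
    return anns


def detect_hosts(
    doc: Document,
    sentences: Sequence[SentenceSpan],
    organism_annotations: Sequence[Annotation],
    aset: Optional[AnnotationSet] = None,
    host_cues: Optional[Sequence[str]] = None,
) -> List[Annotation]:
    """Flag organisms governed by an expression cue as recombinant hosts.

    The cue match must end shortly (< 25 characters) before the organism
    mention in the same sentence, so that a source organism elsewhere in the
    sentence is not swept up.
    """
    if aset is None:
        aset = AnnotationSet("system", doc.doc_id)
    if host_cues is None:
        host_cues = load_list("lists/host_cues.txt")
    cues = [c.casefold() for c in host_cues]
    anns: List[Annotation] = []
    low = doc.text.casefold()
    for sent in sentences:
        s, e = sent.span.start, sent.span.end
        cue_ends: List[int] = []
        seg = low[s:e]
        for cue in cues:
            start = 0
            while True:
                k = seg.find(cue, start)
                if k < 0:
                    break
                cue_ends.append(s + k + len(cue))
                start = k + 1
        if not cue_ends:
            continue
        for org in organism_annotations:
            if not (s <= org.span.start and org.span.end <= e):
                continue
            if any(0 <= org.span.start - ce < 25 for ce in cue_ends):
                feats = {
                    k: v
                    for k, v in org.features.items()
                    if k in {"normalized_name", "taxid", "url", "form", "grounded"}
                }
                anns.append(add_annotation(doc, aset, "Host", org.span, feats))
    return anns
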