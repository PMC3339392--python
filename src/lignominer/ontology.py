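"""Domain-ontology population (ABox) and RDF serialization.

Annotated documents are turned into instance-level triples under a small
domain schema (shipped as ``data/ontology_tbox.ttl``): one individual per
distinct normalized entity — enzymes keyed by EC number (surface as
fallback), organisms by taxid (normalized name as fallback) — plus sentence
individuals carrying character offsets so every mention is traceable to its
provenance.

Relations instantiated: enzyme--fromOrganism (nearest preceding organism
mention, falling back to the document's most frequent organism),
enzyme--hasOptimalTemperature / hasOptimalPH (from optimum extraction),
enzyme--hasSpecificActivity, gene--encodes--enzyme (same sentence with an
"encod*" cue), organism--hasStrain.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
from urllib.parse import quote

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD
from rdflib.compare import to_isomorphic

from .annotations import Annotation, AnnotationSet, Document, Span
from .preprocess import SentenceSpan
from .resources import data_path

__all__ = [
    "LIGNO",
    "populate_ontology",
    "build_external_links",
    "serialize_rdf",
    "load_tbox",
    "graphs_isomorphic",
]

LIGNO = Namespace("https://w3id.org/lignominer/onto#")

_FORMATS = {"turtle": "turtle", "rdfxml": "xml"}

_CLASS_FOR_ETYPE = {
    "Enzyme": "Enzyme",
    "Organism": "Organism",
    "Host": "Host",
    "Gene": "Gene",
    "Substrate": "Substrate",
    "Assay": "Assay",
    "Strain": "Strain",
}


def load_tbox() -> Graph:
    """Parse the shipped schema (classes and properties) into a graph."""
    g = Graph()
    g.parse(data_path("ontology_tbox.ttl"), format="turtle")
    return g


def _uri(klass: str, key: str) -> URIRef:
    return LIGNO[f"{klass}-{quote(key.casefold().replace(' ', '_'), safe='')}"]


def _entity_key(ann: Annotation) -> str:
    if ann.etype == "Enzyme":
        ec = ann.features.get("ec_number", "")
        return f"ec-{ec}" if ec and "|" not in ec else ann.surface.casefold()
    if ann.etype in ("Organism", "Host"):
        taxid = ann.features.get("taxid", "")
        return f"taxid-{taxid}" if taxid else ann.features.get(
            "normalized_name", ann.surface
        ).casefold()
    return ann.surface.casefold()


def build_external_links(individual_features: Dict[str, str]) -> List[str]:
    """Resource URLs for a grounded individual; empty for ungrounded ones."""
    urls = []
    if individual_features.get("url"):
        urls.append(individual_features["url"])
    return urls


def populate_ontology(
    doc: Document,
    aset: AnnotationSet,
    sentences: Optional[Sequence[SentenceSpan]] = None,
) -> Graph:
    """Build the ABox graph for one annotated document."""
    g = Graph()
    g.bind("ligno", LIGNO)
    doc_uri = LIGNO[f"Document-{quote(doc.doc_id, safe='')}"]
    g.add((doc_uri, RDF.type, LIGNO.Document))
    g.add((doc_uri, LIGNO.docId, Literal(doc.doc_id)))

    sentences = list(sentences or [])
    sent_uris: List[Tuple[Span, URIRef]] = []
    for s in sentences:
        su = LIGNO[f"Sentence-{quote(doc.doc_id, safe='')}-{s.index}"]
        sent_uris.append((s.span, su))

    def sentence_of(span: Span) -> Optional[URIRef]:
        for sp, su in sent_uris:
            if sp.start <= span.start and span.end <= sp.end:
                return su
        return None

    used_sentences: Dict[URIRef, Span] = {}

    individuals: Dict[Tuple[str, str], URIRef] = {}
    mention_of: Dict[Tuple[str, str], List[Annotation]] = {}

    for ann in aset:
        klass = _CLASS_FOR_ETYPE.get(ann.etype)
        if klass is None:
            continue
        if klass == "Host":
            klass = "Organism"  # a host is an organism individual in a host role
        key = _entity_key(ann)
        individuals.setdefault((klass, key), _uri(klass, key))
        mention_of.setdefault((klass, key), []).append(ann)

    for (klass, key), uri in individuals.items():
        anns = mention_of[(klass, key)]
        first = anns[0]
        g.add((uri, RDF.type, LIGNO[klass]))
        g.add((uri, LIGNO.inDocument, doc_uri))
        label = first.features.get("recommended_name") or first.features.get(
            "normalized_name"
        ) or first.surface
        g.add((uri, RDFS.label, Literal(label)))
        for fk, prop in (
            ("ec_number", LIGNO.ecNumber),
            ("taxid", LIGNO.taxId),
            ("recommended_name", LIGNO.recommendedName),
            ("systematic_name", LIGNO.systematicName),
            ("swissprot_ids", LIGNO.swissProtId),
        ):
            v = first.features.get(fk)
            if v:
                for part in v.split("|"):
                    g.add((uri, prop, Literal(part)))
        for url in build_external_links(first.features):
            g.add((uri, LIGNO.externalLink, URIRef(url)))
        if any(a.etype == "Host" for a in anns):
            g.add((uri, RDF.type, LIGNO.Host))
        for ann in anns:
            su = sentence_of(ann.span)
            if su is not None:
                g.add((uri, LIGNO.mentionedIn, su))
                used_sentences[su] = next(sp for sp, u in sent_uris if u == su)
            g.add((uri, LIGNO.hasMentionSpan, Literal(f"{ann.span.start}:{ann.span.end}")))

    for su, sp in used_sentences.items():
        g.add((su, RDF.type, LIGNO.Sentence))
        g.add((su, LIGNO.inDocument, doc_uri))
        g.add((su, LIGNO.charStart, Literal(sp.start, datatype=XSD.integer)))
        g.add((su, LIGNO.charEnd, Literal(sp.end, datatype=XSD.integer)))

    def individual_for(ann: Annotation) -> Optional[URIRef]:
        klass = _CLASS_FOR_ETYPE.get(ann.etype)
        if klass == "Host":
            klass = "Organism"
        if klass is None:
            return None
        return individuals.get((klass, _entity_key(ann)))

    enzymes = sorted(aset.by_type("Enzyme"), key=lambda a: a.span.start)
    organisms = sorted(aset.by_type("Organism"), key=lambda a: a.span.start)

    def nearest_enzyme_before(pos: int) -> Optional[Annotation]:
        prior = [a for a in enzymes if a.span.start <= pos]
        if prior:
            return prior[-1]
        if enzymes:
            freq = Counter(_entity_key(a) for a in enzymes)
            best = freq.most_common(1)[0][0]
            return next(a for a in enzymes if _entity_key(a) == best)
        return None

    # enzyme -- fromOrganism
    if organisms:
        freq = Counter(_entity_key(a) for a in organisms)
        most_frequent = next(
            a for a in organisms if _entity_key(a) == freq.most_common(1)[0][0]
        )
        for enz in enzymes:
            prior = [o for o in organisms if o.span.end <= enz.span.start]
            org = prior[-1] if prior else most_frequent
            eu, ou = individual_for(enz), individual_for(org)
            if eu is not None and ou is not None:
                g.add((eu, LIGNO.fromOrganism, ou))

    # optima, specific activity
    for ann in aset:
        if ann.etype in ("Temperature", "pH") and "optimum" in ann.features:
            enz = nearest_enzyme_before(ann.span.start)
            if enz is not None:
                eu = individual_for(enz)
                prop = (
                    LIGNO.hasOptimalTemperature
                    if ann.etype == "Temperature"
                    else LIGNO.hasOptimalPH
                )
                g.add((eu, prop, Literal(float(ann.features["optimum"]))))
        if ann.etype == "SpecificActivity" and "normalized_value" in ann.features:
            enz = nearest_enzyme_before(ann.span.start)
            if enz is not None:
                g.add(
                    (
                        individual_for(enz),
                        LIGNO.hasSpecificActivity,
                        Literal(float(ann.features["normalized_value"])),
                    )
                )

    # gene -- encodes -- enzyme (same sentence, "encod*" cue)
    for gene in aset.by_type("Gene"):
        for sp, su in sent_uris:
            if sp.start <= gene.span.start and gene.span.end <= sp.end:
                segment = doc.text[sp.start : sp.end].casefold()
                if "encod" not in segment:
                    break
                in_sent = [
                    e for e in enzymes if sp.start <= e.span.start and e.span.end <= sp.end
                ]
                gu = individual_for(gene)
                if in_sent and gu is not None:
                    g.add((gu, LIGNO.encodes, individual_for(in_sent[0])))
                break

    # organism -- hasStrain
    for strain in aset.by_type("Strain"):
        su_ = individual_for(strain)
        ref = strain.features.get("attached_organism")
        if su_ is None or not ref:
            continue
        start, end = (int(x) for x in ref.split(":"))
        org = next(
            (o for o in organisms if o.span.start == start and o.span.end == end), None
        )
        if org is not None:
            g.add((individual_for(org), LIGNO.hasStrain, su_))

    return g


def serialize_rdf(graph: Graph, path, format: str = "turtle") -> None:
    """Write a graph as Turtle or RDF/XML; unknown formats are a usage error."""
    fmt = _FORMATS.get(format)
    if fmt is None:
        raise ValueError(f"unknown RDF format {format!r}; expected one of {sorted(_FORMATS)}")
    graph.serialize(destination=str(path), format=fmt, encoding="utf-8")


def graphs_isomorphic(a: Graph, b: Graph) -> bool:
    """RDF graph isomorphism (blank-node safe)."""
    return to_isomorphic(a) == to_isomorphic(b)
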