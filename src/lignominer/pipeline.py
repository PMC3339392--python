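"""End-to-end annotation pipeline: preprocess -> gazetteers -> NER -> contexts.

``annotate_document`` runs the full cascade on raw text and returns the
normalized :class:`Document` together with a "system" annotation set holding
every detected entity, word- and sentence-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .annotations import AnnotationSet, Document
from .config import PipelineConfig, default_config
from .contexts import (
    CueLexicons,
    classify_sentences,
    context_annotations,
    detect_word_level_misc,
    extract_optimum,
    extract_quantities,
)
from .enzyme_ner import (
    detect_abbreviation_definitions,
    detect_enzymes,
    ground_enzyme,
    load_ase_stoplist,
    resolve_abbreviations,
)
from .lexicon import (
    Lexicon,
    compile_enzyme_lexicon,
    compile_taxon_lexicon,
    compile_term_lexicon,
)
from .organism_ner import detect_hosts, detect_organisms, detect_strains
from .preprocess import SentenceSpan, normalize_ligatures, split_sentences, tokenize
from .resources import load_list

__all__ = ["Resources", "load_resources", "annotate_document"]

logger = logging.getLogger(__name__)


@dataclass
class Resources:
    """Compiled lexicons and vocabularies shared across documents."""

    config: PipelineConfig
    enzyme_lexicon: Lexicon
    taxon_lexicon: Lexicon
    substrate_lexicon: Lexicon
    assay_lexicon: Lexicon
    cue_lexicons: CueLexicons
    ase_stoplist: frozenset
    organism_blocklist: List[str] = field(default_factory=list)
    host_cues: List[str] = field(default_factory=list)
    generic_cues: List[str] = field(default_factory=list)
    abbreviations: List[str] = field(default_factory=list)


def load_resources(config: Optional[PipelineConfig] = None) -> Resources:
    """Compile every lexicon and cue list referenced by the configuration."""
    cfg = config or default_config()
    return Resources(
        config=cfg,
        enzyme_lexicon=compile_enzyme_lexicon(cfg.resolve("enzyme_lexicon")),
        taxon_lexicon=compile_taxon_lexicon(cfg.resolve("taxon_lexicon")),
        substrate_lexicon=compile_term_lexicon(cfg.resolve("substrate_lexicon"), "substrate"),
        assay_lexicon=compile_term_lexicon(cfg.resolve("assay_lexicon"), "assay"),
        cue_lexicons=CueLexicons(
            {
                "activity_stability": str(cfg.resolve("cue_activity_stability")),
                "kinetic": str(cfg.resolve("cue_kinetic")),
                "assay_conditions": str(cfg.resolve("cue_assay_conditions")),
                "glycosylation": str(cfg.resolve("cue_glycosylation")),
                "specificity": str(cfg.resolve("cue_specificity")),
                "product": str(cfg.resolve("cue_product")),
            }
        ),
        ase_stoplist=load_ase_stoplist(cfg.resolve("ase_stoplist")),
        organism_blocklist=load_list(cfg.resolve("organism_blocklist")),
        host_cues=load_list(cfg.resolve("host_cues")),
        generic_cues=load_list(cfg.resolve("generic_organism_cues")),
        abbreviations=load_list(cfg.resolve("sentence_abbreviations")),
    )


def annotate_document(
    doc_id: str,
    text: str,
    resources: Optional[Resources] = None,
    set_name: str = "system",
) -> Tuple[Document, AnnotationSet, List[SentenceSpan]]:
    """Run the full pipeline on raw text.

    Stages: ligature normalization, tokenization, sentence splitting, enzyme
    gazetteer + suffix detection, abbreviation definition + coreference,
    grounding, organism/strain/host detection, word-level gazetteers, quantity
    extraction and sentence-level classification with optimum extraction.
    """
    res = resources or load_resources()
    norm, _offsets = normalize_ligatures(text)
    tokens_ = tokenize(norm)
    sentences = split_sentences(norm, tokens_, res.abbreviations)
    doc = Document(doc_id, norm, {"source_length": str(len(text))})
    aset = AnnotationSet(set_name, doc_id)

    # enzymes: gazetteer + suffix, then abbreviation coreference, then grounding
    enzyme_anns = detect_enzymes(doc, tokens_, res.enzyme_lexicon, res.ase_stoplist, aset)
    for ann in enzyme_anns:
        ground_enzyme(ann, res.enzyme_lexicon)
    records = detect_abbreviation_definitions(doc, tokens_, enzyme_anns)
    resolve_abbreviations(doc, tokens_, records, aset)

    # organisms, strains, hosts
    organism_anns = detect_organisms(
        doc,
        tokens_,
        res.taxon_lexicon,
        aset,
        generic_mentions=res.config.generic_organism_mentions,
        blocklist=res.organism_blocklist,
        generic_cues=res.generic_cues,
    )
    detect_strains(doc, tokens_, organism_anns, aset)
    if res.config.host_detection:
        detect_hosts(doc, sentences, organism_anns, aset, res.host_cues)

    # other word-level entities (suppressed inside enzyme/organism mentions)
    claimed = [a.span for a in aset if a.etype in ("Enzyme", "Organism")]
    detect_word_level_misc(
        doc, tokens_, res.substrate_lexicon, res.assay_lexicon, aset, claimed
    )

    # sentence-level contexts
    quantities = [
        extract_quantities(norm[s.span.start : s.span.end], s.span) for s in sentences
    ]
    contexts = classify_sentences(doc, sentences, quantities, res.cue_lexicons, list(aset))
    for ctx in contexts:
        extract_optimum(ctx, doc)
    context_annotations(doc, contexts, aset)

    return doc, aset, sentences
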