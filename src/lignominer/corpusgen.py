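"""Synthetic enzyme-characterization corpus with exact gold annotations.

Real gold corpora for this literature are small and hand-annotated; this
generator assembles articles from parameterized sentence templates that
mirror how purification, optimum, stability, kinetics, expression-host,
substrate-specificity and product-analysis statements are actually phrased,
drawing every entity from the bundled lexicons and recording each insertion
as a gold annotation with exact offsets.

Templates deliberately include the known hard cases: author-coined enzyme
abbreviations reused later in the document, abbreviated genus reuse
("T. reesei" after "Trichoderma reesei"), the "bovine serum albumin"
distractor, stability sentences without optima, filler prose salted with
-ase stoplist words, and an occasional novel "-ase" coinage that only the
suffix rule can see (it is deliberately absent from gold, exercising
precision accounting).

``corrupt_annotations`` produces controlled degradations (drops, 1-3
character boundary shifts, spurious injections) together with an exact
ledger, which serves as an oracle for the evaluator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotations import Annotation, AnnotationSet, Document, Span, add_annotation
from .lexicon import EnzymeLexiconEntry, Lexicon, TaxonLexiconEntry, TermLexiconEntry

__all__ = ["GenerationSpec", "CorruptionLedger", "generate_corpus", "corrupt_annotations"]


@dataclass
class GenerationSpec:
    """Parameters of the synthetic corpus."""

    seed: int = 17
    n_docs: int = 20
    enzymes_per_doc: int = 10
    organisms_per_doc: int = 4
    substrates_per_doc: int = 3
    assays_per_doc: int = 1
    drop_rate: float = 0.0
    boundary_shift_rate: float = 0.0
    spurious_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("drop_rate", "boundary_shift_rate", "spurious_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_docs", "enzymes_per_doc", "organisms_per_doc",
                     "substrates_per_doc", "assays_per_doc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CorruptionLedger:
    """Exact realized corruption counts (the evaluator oracle)."""

    kept_exact: int = 0
    shifted: int = 0
    dropped: int = 0
    injected: int = 0
    per_type: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def bump(self, etype: str, event: str) -> None:
        setattr(self, event, getattr(self, event) + 1)
        rec = self.per_type.setdefault(
            etype, {"kept_exact": 0, "shifted": 0, "dropped": 0, "injected": 0}
        )
        rec[event] += 1


# short forms must pass the in-order letter-subsequence validation
_SHORT_FORMS = {
    "endoglucanase": "EG",
    "cellobiohydrolase": "CBH",
    "beta-glucosidase": "BGL",
    "xylanase": "XYL",
    "beta-xylosidase": "BXL",
    "alpha-galactosidase": "AGL",
    "laccase": "LAC",
    "lignin peroxidase": "LiP",
    "manganese peroxidase": "MnP",
    "glucoamylase": "GA",
}

_FILLER = [
    "These results increase our understanding of biomass conversion.",
    "Previous reports describe a similar case in a different database.",
    "The disease resistance phenotype was not examined in this phase of the work.",
    "Protein samples were stored at low temperature until use.",
    "All experiments were repeated three times.",
    "The release of reducing ends was monitored over time.",
    "Column fractions were pooled and concentrated.",
]

_NOVEL_ASE = ["frobase", "grindase"]  # unknown coinages: suffix-rule FPs by design


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: List[str] = []
        self.pos = 0
        self.gold: List[Tuple[str, int, int, Dict[str, str]]] = []

    def add_sentence(self, text: str, anns: Sequence[Tuple[str, int, int, Dict[str, str]]] = ()):
        start = self.pos
        self.parts.append(text)
        for etype, rel_start, rel_end, feats in anns:
            self.gold.append((etype, start + rel_start, start + rel_end, dict(feats)))
        self.pos += len(text) + 1  # single space joiner

    def sentence_bounds(self, text: str) -> Tuple[int, int]:
        return 0, len(text)

    def build(self) -> Tuple[Document, AnnotationSet]:
        text = " ".join(self.parts)
        doc = Document(self.doc_id, text)
        aset = AnnotationSet("gold", self.doc_id)
        for etype, start, end, feats in self.gold:
            add_annotation(doc, aset, etype, Span(start, end), feats)
        return doc, aset


def _pick_enzymes(rng: random.Random, lexicon: Lexicon, k: int) -> List[EnzymeLexiconEntry]:
    entries = [e for e in lexicon.entries if isinstance(e, EnzymeLexiconEntry)]
    return rng.sample(entries, min(k, len(entries)))


def generate_corpus(
    spec: GenerationSpec,
    enzyme_lexicon: Lexicon,
    taxon_lexicon: Lexicon,
    substrate_lexicon: Lexicon,
    assay_lexicon: Lexicon,
) -> List[Tuple[Document, AnnotationSet]]:
    """Generate documents with exact gold annotations; deterministic per seed."""
    rng = random.Random(spec.seed)
    species = [
        e for e in taxon_lexicon.entries
        if isinstance(e, TaxonLexiconEntry) and len(e.scientific_name.split()) == 2
    ]
    genera = [
        e for e in taxon_lexicon.entries
        if isinstance(e, TaxonLexiconEntry) and len(e.scientific_name.split()) == 1
        and e.scientific_name[0].isupper()
    ]
    substrates = [e for e in substrate_lexicon.entries if isinstance(e, TermLexiconEntry)]
    assays = [e for e in assay_lexicon.entries if isinstance(e, TermLexiconEntry)]
    if spec.enzymes_per_doc and not enzyme_lexicon.entries:
        raise ValueError("enzyme frequency requested but enzyme lexicon is empty")
    if spec.organisms_per_doc and not species:
        raise ValueError("organism frequency requested but taxon lexicon has no species")
    if spec.substrates_per_doc and not substrates:
        raise ValueError("substrate frequency requested but substrate lexicon is empty")
    if spec.assays_per_doc and not assays:
        raise ValueError("assay frequency requested but assay lexicon is empty")

    any_entities = bool(
        spec.enzymes_per_doc or spec.organisms_per_doc
        or spec.substrates_per_doc or spec.assays_per_doc
    )
    corpus: List[Tuple[Document, AnnotationSet]] = []
    for d in range(spec.n_docs):
        b = _DocBuilder(f"synth-{spec.seed:04d}-{d:03d}")
        if not any_entities:
            for s in rng.sample(_FILLER, 4):
                b.add_sentence(s)
            corpus.append(b.build())
            continue
        enzymes = _pick_enzymes(rng, enzyme_lexicon, max(spec.enzymes_per_doc // 2, 1)) \
            if spec.enzymes_per_doc else []
        orgs = rng.sample(species, min(spec.organisms_per_doc, len(species))) \
            if spec.organisms_per_doc else []
        subs = rng.sample(substrates, min(spec.substrates_per_doc, len(substrates))) \
            if spec.substrates_per_doc else []
        says = rng.sample(assays, min(spec.assays_per_doc, len(assays))) \
            if spec.assays_per_doc else []

        enzyme_budget = spec.enzymes_per_doc
        main_enzyme = enzymes[0] if enzymes else None
        main_org = orgs[0] if orgs else None
        host = orgs[1] if len(orgs) > 1 else None

        def enzyme_feats(e: EnzymeLexiconEntry) -> Dict[str, str]:
            return {"ec_number": e.ec_number, "recommended_name": e.recommended_name}

        # 1. purification sentence with author abbreviation
        if main_enzyme is not None and main_org is not None and enzyme_budget > 0:
            name = main_enzyme.recommended_name
            short = _SHORT_FORMS.get(name)
            org = main_org.scientific_name
            if short:
                text = (
                    f"The extracellular {name} ({short}) was purified to homogeneity "
                    f"from the culture supernatant of {org}."
                )
            else:
                text = (
                    f"The extracellular {name} was purified to homogeneity "
                    f"from the culture supernatant of {org}."
                )
            e_start = text.index(name)
            o_start = text.index(org)
            anns = [
                ("Enzyme", e_start, e_start + len(name), enzyme_feats(main_enzyme)),
                ("Organism", o_start, o_start + len(org), {"taxid": str(main_org.taxid)}),
            ]
            b.add_sentence(text, anns)
            enzyme_budget -= 1

            # 2. specific-activity sentence reusing the abbreviation
            sa = round(rng.uniform(5, 200), 2)
            if short:
                text = f"The purified {short} had a specific activity of {sa} U/mg protein."
                s_start = text.index(short)
                b.add_sentence(
                    text,
                    [
                        ("Enzyme", s_start, s_start + len(short),
                         {**enzyme_feats(main_enzyme), "source": "abbreviation"}),
                        ("SpecificActivity", 0, len(text), {"normalized_value": str(sa)}),
                    ],
                )
                enzyme_budget -= 1
            else:
                text = f"The purified enzyme had a specific activity of {sa} U/mg protein."
                b.add_sentence(text, [("SpecificActivity", 0, len(text), {"normalized_value": str(sa)})])

        # 3. temperature optimum + profile
        t_opt = rng.choice([40, 45, 50, 55, 60, 65, 70])
        p1, p2 = rng.choice([(84, 29), (75, 40), (90, 55)])
        text = (
            f"The purified enzyme exhibited maximum activity at {t_opt}°C, with "
            f"{p1}% relative activity at {t_opt + 5}°C and {p2}% activity at {t_opt + 15}°C."
        )
        b.add_sentence(text, [("Temperature", 0, len(text), {"optimum": str(t_opt)})])

        # 4. pH optimum (second enzyme if available)
        ph_opt = rng.choice([3.0, 4.0, 4.5, 5.0, 5.5, 6.0, 7.0])
        lo = round(max(1.0, ph_opt - 2.0), 1)
        pr = rng.choice([70, 80, 85])
        if len(enzymes) > 1 and enzyme_budget > 0:
            nm = enzymes[1].recommended_name
            text = (
                f"The {nm} displayed an optimum activity at pH {ph_opt} and retained "
                f"{pr}% activity at pH {lo}."
            )
            e_start = text.index(nm)
            b.add_sentence(
                text,
                [
                    ("Enzyme", e_start, e_start + len(nm), enzyme_feats(enzymes[1])),
                    ("pH", 0, len(text), {"optimum": str(ph_opt)}),
                ],
            )
            enzyme_budget -= 1
        else:
            text = (
                f"The enzyme displayed an optimum activity at pH {ph_opt} and retained "
                f"{pr}% activity at pH {lo}."
            )
            b.add_sentence(text, [("pH", 0, len(text), {"optimum": str(ph_opt)})])

        # 5. stability sentence (pH context without an optimum)
        hi = round(min(12.0, ph_opt + 3.0), 1)
        text = (
            f"The enzyme retained greater than 90% of its original activity between "
            f"pH {lo} and {hi} at room temperature for 3 h."
        )
        b.add_sentence(text, [("pH", 0, len(text), {})])

        # 6. kinetics sentence
        text = (
            f"The Km and kcat values were determined in 0.1 M citrate buffer "
            f"at pH {ph_opt} and {t_opt}°C."
        )
        b.add_sentence(text, [("KineticAssayConditions", 0, len(text), {}),
                              ("ActivityAssayConditions", 0, len(text), {})])

        # 7. expression host with gene
        if host is not None and main_enzyme is not None and enzyme_budget > 0:
            gene = f"{main_enzyme.recommended_name[:3].lower().replace('-', 'x')}{rng.randint(1, 99)}{rng.choice('ABCDEF')}"
            nm = main_enzyme.recommended_name
            hostname = host.scientific_name
            text = f"The {gene} gene encoding the {nm} was expressed in {hostname}."
            g_start = text.index(gene)
            e_start = text.index(nm, g_start + len(gene))
            h_start = text.index(hostname)
            b.add_sentence(
                text,
                [
                    ("Gene", g_start, g_start + len(gene), {}),
                    ("Enzyme", e_start, e_start + len(nm), enzyme_feats(main_enzyme)),
                    ("Organism", h_start, h_start + len(hostname), {"taxid": str(host.taxid)}),
                    ("Host", h_start, h_start + len(hostname), {"taxid": str(host.taxid)}),
                ],
            )
            enzyme_budget -= 1

        # 8. strain sentence: "Genus sp. F75 was grown on <substrate>."
        if genera and subs:
            genus = rng.choice(genera).scientific_name
            strain = f"F{rng.randint(10, 99)}"
            sub = subs[0].name
            text = f"{genus} sp. {strain} was grown on {sub} as the sole carbon source."
            st_start = text.index(strain)
            sub_start = text.index(sub)
            b.add_sentence(
                text,
                [
                    ("Organism", 0, len(f"{genus} sp."), {"form": "genus_sp"}),
                    ("Strain", st_start, st_start + len(strain), {}),
                    ("Substrate", sub_start, sub_start + len(sub), {}),
                ],
            )

        # 9. substrate specificity (third enzyme + second organism)
        if len(subs) > 1 and enzyme_budget > 0:
            e = enzymes[min(2, len(enzymes) - 1)]
            nm = e.recommended_name
            org = (orgs[2] if len(orgs) > 2 else main_org)
            sub = subs[1].name
            if org is not None:
                text = f"The {nm} from {org.scientific_name} had highest activity on {sub}."
                e_start = text.index(nm)
                o_start = text.index(org.scientific_name)
                sub_start = text.index(sub)
                b.add_sentence(
                    text,
                    [
                        ("Enzyme", e_start, e_start + len(nm), enzyme_feats(e)),
                        ("Organism", o_start, o_start + len(org.scientific_name),
                         {"taxid": str(org.taxid)}),
                        ("Substrate", sub_start, sub_start + len(sub), {}),
                        ("SubstrateSpecificity", 0, len(text), {}),
                    ],
                )
                enzyme_budget -= 1

        # 10. abbreviated genus reuse
        if main_org is not None:
            genus, epithet = main_org.scientific_name.split()[:2]
            abbrev = f"{genus[0]}. {epithet}"
            text = f"Enzyme production by {abbrev} peaked after five days of cultivation."
            a_start = text.index(abbrev)
            b.add_sentence(
                text,
                [("Organism", a_start, a_start + len(abbrev),
                  {"form": "abbreviated", "normalized_name": main_org.scientific_name})],
            )

        # 11. assay sentence
        if says:
            assay = says[0].name
            text = f"Reducing sugars were quantified by the {assay}."
            a_start = text.index(assay)
            b.add_sentence(text, [("Assay", a_start, a_start + len(assay), {})])

        # 12. glycosylation + product analysis
        text = "SDS-PAGE analysis indicated that the purified protein was N-glycosylated."
        b.add_sentence(text, [("Glycosylation", 0, len(text), {})])
        text = "Analysis of the reaction showed that oligomers were released as the main products."
        b.add_sentence(text, [("ProductAnalysis", 0, len(text), {})])

        # 13. remaining enzyme mentions in plain context sentences
        while enzyme_budget > 0 and enzymes:
            e = enzymes[enzyme_budget % len(enzymes)]
            nm = e.recommended_name
            text = f"A commercial {nm} preparation served as the reference standard."
            e_start = text.index(nm)
            b.add_sentence(text, [("Enzyme", e_start, e_start + len(nm), enzyme_feats(e))])
            enzyme_budget -= 1

        # 14. distractors and filler
        if spec.assays_per_doc:
            distractor = (
                "Soluble protein was determined according to the Bradford assay using "
                "bovine serum albumin as standard."
            )
            br = distractor.index("Bradford assay")
            b.add_sentence(distractor, [("Assay", br, br + len("Bradford assay"), {})])
        if d % 4 == 0:
            coin = _NOVEL_ASE[d % len(_NOVEL_ASE)]
            b.add_sentence(f"A faint band suggested an additional {coin} species.")
        for s in rng.sample(_FILLER, 3):
            b.add_sentence(s)

        corpus.append(b.build())
    return corpus


def corrupt_annotations(
    doc: Document,
    gold: AnnotationSet,
    rates: Tuple[float, float, float],
    seed: int,
) -> Tuple[AnnotationSet, CorruptionLedger]:
    """Degrade a gold set into a simulated system set, with an exact ledger.

    ``rates`` is (drop, boundary_shift, spurious).  Shifted spans still
    overlap their source annotation, never coincide with it, and never touch
    another same-type gold span — so strict true positives equal
    ``kept_exact`` and lenient true positives equal ``kept_exact + shifted``
    by construction.  Injected spurious spans overlap no same-type gold span.
    """
    drop, shift, spurious = rates
    for name, v in (("drop", drop), ("shift", shift), ("spurious", spurious)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} rate must be in [0, 1]")
    rng = random.Random(seed)
    out = AnnotationSet("degraded", gold.doc_id)
    ledger = CorruptionLedger()
    text_len = len(doc.text)
    by_type: Dict[str, List[Span]] = {}
    for ann in gold:
        by_type.setdefault(ann.etype, []).append(ann.span)

    def same_type_conflict(etype: str, span: Span, skip: Span) -> bool:
        return any(
            s != skip and span.overlaps(s) for s in by_type.get(etype, [])
        )

    placed_by_type: Dict[str, List[Span]] = {}

    for ann in gold:
        r = rng.random()
        if r < drop:
            ledger.bump(ann.etype, "dropped")
            continue
        if r < drop + shift:
            new_span = None
            for _ in range(20):
                ds = rng.choice([-3, -2, -1, 0, 1, 2, 3])
                de = rng.choice([-3, -2, -1, 0, 1, 2, 3])
                s, e = ann.span.start + ds, ann.span.end + de
                if (s, e) == (ann.span.start, ann.span.end):
                    continue
                if not (0 <= s < e <= text_len):
                    continue
                cand = Span(s, e)
                if not cand.overlaps(ann.span):
                    continue
                if same_type_conflict(ann.etype, cand, ann.span):
                    continue
                if any(cand.overlaps(p) for p in placed_by_type.get(ann.etype, [])):
                    continue
                new_span = cand
                break
            if new_span is None:
                out.add(Annotation(ann.etype, ann.span, ann.surface, dict(ann.features)))
                placed_by_type.setdefault(ann.etype, []).append(ann.span)
                ledger.bump(ann.etype, "kept_exact")
            else:
                surf = doc.text[new_span.start : new_span.end]
                out.add(Annotation(ann.etype, new_span, surf, dict(ann.features)))
                placed_by_type.setdefault(ann.etype, []).append(new_span)
                ledger.bump(ann.etype, "shifted")
            continue
        out.add(Annotation(ann.etype, ann.span, ann.surface, dict(ann.features)))
        placed_by_type.setdefault(ann.etype, []).append(ann.span)
        ledger.bump(ann.etype, "kept_exact")

    # spurious injections: same-type spans overlapping no gold and no placed span
    for ann in gold:
        if rng.random() >= spurious:
            continue
        for _ in range(50):
            length = rng.randint(3, 8)
            start = rng.randint(0, max(0, text_len - length - 1))
            cand = Span(start, start + length)
            if any(cand.overlaps(s) for s in by_type.get(ann.etype, [])):
                continue
            if any(cand.overlaps(p) for p in placed_by_type.get(ann.etype, [])):
                continue
            out.add(
                Annotation(ann.etype, cand, doc.text[cand.start : cand.end], {"source": "spurious"})
            )
            placed_by_type.setdefault(ann.etype, []).append(cand)
            ledger.bump(ann.etype, "injected")
            break
    return out, ledger
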