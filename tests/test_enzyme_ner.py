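"""Enzyme detection, abbreviation coreference and grounding tests."""

import pytest

from lignominer.annotations import AnnotationSet, Document, Span
from lignominer.enzyme_ner import (
    abbreviation_miss_report,
    detect_abbreviation_definitions,
    detect_enzymes,
    detect_suffix_candidates,
    ground_enzyme,
    load_ase_stoplist,
    resolve_abbreviations,
)
from lignominer.preprocess import tokenize

from conftest import EG_PASSAGE


@pytest.fixture(scope="module")
def stoplist():
    return load_ase_stoplist()


def run_enzyme_stage(text, resources, doc_id="t"):
    doc = Document(doc_id, text)
    toks = tokenize(text)
    aset = AnnotationSet("system", doc_id)
    anns = detect_enzymes(doc, toks, resources.enzyme_lexicon, resources.ase_stoplist, aset)
    for a in anns:
        ground_enzyme(a, resources.enzyme_lexicon)
    records = detect_abbreviation_definitions(doc, toks, anns)
    resolve_abbreviations(doc, toks, records, aset)
    return doc, aset


class TestSuffixRule:
    @pytest.mark.parametrize("word", ["xylanases", "frobase", "Endoglucanase"])
    def test_candidates_detected(self, word, stoplist):
        assert detect_suffix_candidates(tokenize(word), stoplist)

    @pytest.mark.parametrize(
        "word", ["disease", "increase", "phase", "database", "base", "case", "release"]
    )
    def test_english_false_positives_filtered(self, word, stoplist):
        assert detect_suffix_candidates(tokenize(word), stoplist) == []

    def test_plain_english_paragraph_yields_no_candidates(self, stoplist):
        text = (
            "In any case the increase was a phase effect; the database release "
            "did not cease, please see the phrase above."
        )
        assert detect_suffix_candidates(tokenize(text), stoplist) == []


class TestDetection:
    def test_gazetteer_hit(self, resources):
        doc, aset = run_enzyme_stage("The alpha-galactosidase was purified.", resources)
        anns = aset.by_type("Enzyme")
        assert len(anns) == 1 and anns[0].surface == "alpha-galactosidase"
        assert anns[0].features["ec_number"] == "3.2.1.22"

    def test_no_candidates_in_neutral_text(self, resources):
        doc, aset = run_enzyme_stage("The results were reproducible.", resources)
        assert aset.by_type("Enzyme") == []

    def test_gazetteer_wins_over_suffix_candidate(self, resources):
        doc, aset = run_enzyme_stage("The endoglucanase was active.", resources)
        anns = aset.by_type("Enzyme")
        assert len(anns) == 1 and anns[0].features["source"] == "gazetteer"

    def test_determinism(self, resources):
        a = run_enzyme_stage(EG_PASSAGE, resources)[1]
        b = run_enzyme_stage(EG_PASSAGE, resources)[1]
        assert [(x.etype, x.span, x.features) for x in a] == [
            (x.etype, x.span, x.features) for x in b
        ]


class TestAbbreviations:
    def test_definition_detected_in_purification_passage(self, resources):
        doc = Document("t", EG_PASSAGE)
        toks = tokenize(EG_PASSAGE)
        aset = AnnotationSet("system", "t")
        anns = detect_enzymes(doc, toks, resources.enzyme_lexicon, resources.ase_stoplist, aset)
        records = detect_abbreviation_definitions(doc, toks, anns)
        assert len(records) == 1
        assert records[0].short_surface == "EG"
        assert records[0].long_surface == "endoglucanase"

    def test_figure_reference_not_a_definition(self, resources):
        text = "The endoglucanase (Fig. 2) was active."
        doc = Document("t", text)
        toks = tokenize(text)
        aset = AnnotationSet("system", "t")
        anns = detect_enzymes(doc, toks, resources.enzyme_lexicon, resources.ase_stoplist, aset)
        assert detect_abbreviation_definitions(doc, toks, anns) == []

    def test_subsequence_validation(self, resources):
        text = "The beta-glucosidase (BGL) and the xylanase (QQQ) were assayed."
        doc = Document("t", text)
        toks = tokenize(text)
        aset = AnnotationSet("system", "t")
        anns = detect_enzymes(doc, toks, resources.enzyme_lexicon, resources.ase_stoplist, aset)
        records = detect_abbreviation_definitions(doc, toks, anns)
        assert [r.short_surface for r in records] == ["BGL"]  # QQQ is not a subsequence

    def test_coreference_copies_grounding(self, resources):
        doc, aset = run_enzyme_stage(EG_PASSAGE, resources)
        eg = [a for a in aset.by_type("Enzyme") if a.surface == "EG"]
        assert len(eg) == 1
        ann = eg[0]
        assert ann.features["source"] == "abbreviation"
        assert ann.features["antecedent_surface"] == "endoglucanase"
        assert ann.features["ec_number"] == "3.2.1.4"
        # antecedent span points at the defining full form
        start, end = (int(x) for x in ann.features["antecedent_span"].split(":"))
        assert doc.text[start:end] == "endoglucanase"

    def test_short_form_before_definition_not_annotated(self, resources):
        text = (
            "EG activity was reported earlier. The extracellular endoglucanase (EG) "
            "was purified. The EG was stable."
        )
        doc, aset = run_enzyme_stage(text, resources)
        eg_anns = [a for a in aset.by_type("Enzyme") if a.surface == "EG"]
        # only the post-definition standalone occurrence
        assert len(eg_anns) == 1
        assert eg_anns[0].span.start > text.index("(EG)")

    def test_unused_definition_adds_nothing(self, resources):
        text = "The extracellular endoglucanase (EG) was purified to homogeneity."
        doc, aset = run_enzyme_stage(text, resources)
        assert [a.surface for a in aset.by_type("Enzyme")] == ["endoglucanase"]


class TestGrounding:
    def test_plural_stripped_on_failed_lookup(self, resources):
        doc, aset = run_enzyme_stage("Several xylanases were secreted.", resources)
        anns = aset.by_type("Enzyme")
        assert anns and anns[0].features.get("ec_number") == "3.2.1.8"

    def test_unknown_suffix_candidate_stays_ungrounded(self, resources):
        doc, aset = run_enzyme_stage("A novel frobase was detected.", resources)
        anns = aset.by_type("Enzyme")
        assert anns[0].features["grounded"] == "false"
        assert anns[0].features["source"] == "suffix_rule"
        assert "ec_number" not in anns[0].features

    def test_ambiguous_synonym_lists_both_ecs(self, tmp_path, resources):
        from lignominer.lexicon import compile_enzyme_lexicon

        table = tmp_path / "amb.tsv"
        table.write_text(
            "recommended_name\tsystematic_name\tec_number\tsynonyms\tswissprot_ids\turl\n"
            "endoglucanase\t\t3.2.1.4\tCMCase\t\t\n"
            "cellodextrinase\t\t3.2.1.74\tCMCase\t\t\n"
        )
        lex = compile_enzyme_lexicon(table)
        text = "High CMCase activity was found."
        doc = Document("t", text)
        toks = tokenize(text)
        aset = AnnotationSet("system", "t")
        anns = detect_enzymes(doc, toks, lex, load_ase_stoplist(), aset)
        target = [a for a in anns if a.surface == "CMCase"]
        g = ground_enzyme(target[0], lex)
        assert g.ambiguous
        assert target[0].features["ambiguous"] == "true"
        assert set(target[0].features["ec_number"].split("|")) == {"3.2.1.4", "3.2.1.74"}


def test_abbreviation_miss_report_fraction(resources):
    doc = Document("t", "The endoglucanase and the EG and the xylanase were active.")
    gold = AnnotationSet("gold", "t")
    system = AnnotationSet("system", "t")
    from lignominer.annotations import add_annotation

    t = doc.text
    for surf in ("endoglucanase", "EG", "xylanase"):
        i = t.index(surf)
        add_annotation(doc, gold, "Enzyme", Span(i, i + len(surf)))
    i = t.index("endoglucanase")
    add_annotation(doc, system, "Enzyme", Span(i, i + len("endoglucanase")))
    i = t.index("xylanase")
    add_annotation(doc, system, "Enzyme", Span(i, i + len("xylanase")))
    report = abbreviation_miss_report(gold, system)
    assert report["false_negatives"] == 1
    assert report["abbreviation_like"] == 1
    assert report["fraction"] == 1.0
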