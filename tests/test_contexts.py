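"""Quantity extraction and sentence-level context classification tests."""

import random
import re

import pytest

from lignominer.annotations import AnnotationSet, Document, Span
from lignominer.contexts import (
    ContextSentence,
    classify_sentences,
    detect_word_level_misc,
    extract_optimum,
    extract_profile_pairs,
    extract_quantities,
)
from lignominer.pipeline import annotate_document
from lignominer.preprocess import split_sentences, tokenize

from conftest import PH_SENTENCE, STABILITY_SENTENCE, TEMPERATURE_SENTENCE


def quantities_of(text):
    return extract_quantities(text, Span(0, len(text)))


class TestQuantityExtraction:
    def test_temperature_profile_sentence(self):
        qs = quantities_of(TEMPERATURE_SENTENCE)
        temps = [q.value for q in qs if q.kind == "temperature_C"]
        pcts = [q.value for q in qs if q.kind == "relative_activity_pct"]
        assert temps == [55.0, 60.0, 70.0]
        assert pcts == [84.0, 29.0]

    def test_ph_range(self):
        qs = quantities_of("The enzyme was stable between pH 2.0 and 7.0 for 3 h.")
        ph = [q for q in qs if q.kind == "pH"]
        assert len(ph) == 1
        assert ph[0].value == 2.0 and ph[0].range_hi == 7.0

    def test_specific_activity(self):
        qs = quantities_of("The purified EG (specific activity 43.33 U/mg protein) was pure.")
        sa = [q for q in qs if q.kind == "specific_activity_U_per_mg"]
        assert [q.value for q in sa] == [43.33]
        assert sa[0].text_value == "43.33"

    def test_molar_concentration_case_sensitive(self):
        qs = quantities_of("Assays used 0.1 M buffer on Bio-Gel A-0.5 m columns.")
        molar = [q.value for q in qs if q.kind == "molar_conc"]
        assert molar == [0.1]  # lowercase "m" is a length unit, not molarity

    def test_spaced_thousands_parse(self):
        qs = quantities_of("A molecular weight of 27 000 was observed at 55°C.")
        assert [q.value for q in qs if q.kind == "temperature_C"] == [55.0]

    def test_implausible_ph_flagged(self):
        qs = quantities_of("An apparent pH 16 reading was discarded.")
        assert qs[0].flagged

    def test_spans_lie_within_sentence(self):
        span = Span(100, 100 + len(TEMPERATURE_SENTENCE))
        qs = extract_quantities(TEMPERATURE_SENTENCE, span)
        for q in qs:
            assert span.start <= q.span.start < q.span.end <= span.end

    def test_brute_force_regex_oracle_on_generated_sentences(self):
        # oracle: counts of unit mentions found by naive unit-by-unit scans
        rng = random.Random(1)
        for _ in range(1000):
            t = rng.randint(20, 90)
            p = rng.randint(5, 99)
            ph = round(rng.uniform(2, 9), 1)
            sa = round(rng.uniform(0.5, 300), 2)
            text = (
                f"Activity was {p}% at {t}°C and pH {ph}; the specific activity "
                f"was {sa} U/mg under these conditions."
            )
            qs = quantities_of(text)
            by_kind = {}
            for q in qs:
                by_kind.setdefault(q.kind, []).append(q.value)
            assert by_kind["temperature_C"] == [float(t)]
            assert by_kind["relative_activity_pct"] == [float(p)]
            assert by_kind["pH"] == [ph]
            assert by_kind["specific_activity_U_per_mg"] == [sa]


def classify_one(text, resources, word_anns=()):
    doc = Document("t", text)
    toks = tokenize(text)
    sents = split_sentences(text, toks)
    qs = [extract_quantities(text[s.span.start : s.span.end], s.span) for s in sents]
    return doc, classify_sentences(doc, sents, qs, resources.cue_lexicons, word_anns)


class TestClassification:
    def test_ph_sentence(self, resources):
        doc, ctxs = classify_one(PH_SENTENCE, resources)
        assert {c.etype for c in ctxs} == {"pH"}

    def test_temperature_from_stability_sentence(self, resources):
        doc, ctxs = classify_one(STABILITY_SENTENCE, resources)
        assert "Temperature" in {c.etype for c in ctxs}
        # "different pH values" has no pH quantity -> no pH context
        assert "pH" not in {c.etype for c in ctxs}

    def test_substrate_specificity_needs_entity_mention(self, resources):
        text = "The Endoglucanase from Pyrococcus furiosus had highest activity on cellopentaose."
        doc, aset, _ = annotate_document("t", text)
        ctx_types = {a.etype for a in aset}
        assert "SubstrateSpecificity" in ctx_types

    def test_glycosylation_morpheme(self, resources):
        doc, ctxs = classify_one("The protein was shown to be N-glycosylated.", resources)
        assert {c.etype for c in ctxs} == {"Glycosylation"}

    def test_kinetic_conditions(self, resources):
        text = "Km and kcat were determined in 0.1 M citrate buffer at pH 4.0 and 37°C."
        doc, ctxs = classify_one(text, resources)
        types = {c.etype for c in ctxs}
        assert "KineticAssayConditions" in types
        assert "ActivityAssayConditions" in types  # buffer + conditions

    def test_product_analysis(self, resources):
        doc, ctxs = classify_one(
            "HPLC analysis showed that glucose and galactose were released.", resources
        )
        assert {c.etype for c in ctxs} == {"ProductAnalysis"}

    def test_quantities_within_sentence_property(self, resources):
        text = f"{TEMPERATURE_SENTENCE} {PH_SENTENCE}"
        doc, ctxs = classify_one(text, resources)
        for ctx in ctxs:
            for q in ctx.quantities:
                assert ctx.span.start <= q.span.start < q.span.end <= ctx.span.end

    def test_temperature_iff_quantity_plus_cue(self, resources):
        # exhaustively checkable rule on constructed minimal pairs
        with_cue = "The enzyme retained activity at 50°C."
        without_cue = "Samples were shipped at 4°C."
        without_qty = "The enzyme retained most activity after heating."
        assert {c.etype for c in classify_one(with_cue, resources)[1]} >= {"Temperature"}
        assert "Temperature" not in {c.etype for c in classify_one(without_cue, resources)[1]}
        assert "Temperature" not in {c.etype for c in classify_one(without_qty, resources)[1]}


class TestOptimum:
    def _context(self, text, etype, resources):
        doc, ctxs = classify_one(text, resources)
        matching = [c for c in ctxs if c.etype == etype]
        assert matching
        return doc, matching[0]

    def test_temperature_optimum(self, resources):
        doc, ctx = self._context(TEMPERATURE_SENTENCE, "Temperature", resources)
        extract_optimum(ctx, doc)
        assert ctx.optimum is not None and ctx.optimum.value == 55.0

    def test_ph_optimum(self, resources):
        doc, ctx = self._context(PH_SENTENCE, "pH", resources)
        extract_optimum(ctx, doc)
        assert ctx.optimum is not None and ctx.optimum.value == 5.0

    def test_stability_sentence_has_no_optimum(self, resources):
        doc, ctx = self._context(STABILITY_SENTENCE, "Temperature", resources)
        extract_optimum(ctx, doc)
        assert ctx.optimum is None

    def test_optimum_comes_from_sentence_quantities(self, resources):
        doc, ctx = self._context(TEMPERATURE_SENTENCE, "Temperature", resources)
        extract_optimum(ctx, doc)
        assert ctx.optimum in ctx.quantities


class TestProfilePairs:
    def test_temperature_pairs(self, resources):
        doc, ctxs = classify_one(TEMPERATURE_SENTENCE, resources)
        ctx = [c for c in ctxs if c.etype == "Temperature"][0]
        assert extract_profile_pairs(ctx, doc) == [(60.0, 84.0), (70.0, 29.0)]

    def test_single_percentage_distributes_over_coordination(self, resources):
        doc, ctxs = classify_one(PH_SENTENCE, resources)
        ctx = [c for c in ctxs if c.etype == "pH"][0]
        assert extract_profile_pairs(ctx, doc) == [(3.0, 80.0), (8.0, 80.0)]

    def test_no_percentages_yields_empty(self, resources):
        doc, ctxs = classify_one(
            "The enzyme showed maximum activity at 55°C in all assays.", resources
        )
        ctx = [c for c in ctxs if c.etype == "Temperature"][0]
        assert extract_profile_pairs(ctx, doc) == []


class TestWordLevelMisc:
    def test_assay_gazetteer(self, resources):
        text = "Sugars were measured by the Dinitrosalicylic Acid Method."
        doc = Document("t", text)
        aset = AnnotationSet("system", "t")
        detect_word_level_misc(
            doc, tokenize(text), resources.substrate_lexicon, resources.assay_lexicon, aset
        )
        assert [a.surface for a in aset.by_type("Assay")] == ["Dinitrosalicylic Acid Method"]

    def test_gene_shape_with_cue(self, resources):
        text = "Expression of the mel36F gene was induced."
        doc = Document("t", text)
        aset = AnnotationSet("system", "t")
        detect_word_level_misc(
            doc, tokenize(text), resources.substrate_lexicon, resources.assay_lexicon, aset
        )
        assert [a.surface for a in aset.by_type("Gene")] == ["mel36F"]

    def test_substrate_gazetteer(self, resources):
        text = "Hydrolysis of stachyose was complete."
        doc = Document("t", text)
        aset = AnnotationSet("system", "t")
        detect_word_level_misc(
            doc, tokenize(text), resources.substrate_lexicon, resources.assay_lexicon, aset
        )
        assert [a.surface for a in aset.by_type("Substrate")] == ["stachyose"]

    def test_exclusion_spans_suppress_nested_matches(self, resources):
        text = "High cellobiose dehydrogenase activity was measured on cellobiose."
        doc = Document("t", text)
        enzyme_span = Span(5, 5 + len("cellobiose dehydrogenase"))
        aset = AnnotationSet("system", "t")
        detect_word_level_misc(
            doc, tokenize(text), resources.substrate_lexicon, resources.assay_lexicon,
            aset, [enzyme_span],
        )
        subs = aset.by_type("Substrate")
        assert len(subs) == 1 and subs[0].span.start > enzyme_span.end
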