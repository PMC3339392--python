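"""Strict/lenient evaluation, corpus statistics and agreement tests."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from lignominer.annotations import Annotation, AnnotationSet, Span
from lignominer.evaluation import (
    MatchCounts,
    align,
    compute_metrics,
    corpus_statistics,
    inter_annotator_agreement,
)


def make_set(name, spans, etype="Enzyme", doc_id="d1"):
    aset = AnnotationSet(name, doc_id)
    for s, e in spans:
        aset.add(Annotation(etype, Span(s, e), surface="x" * (e - s)))
    return aset


def brute_force_max_matching(gold_spans, sys_spans):
    """Oracle: enumerate all injective pairings of overlapping pairs."""
    edges = [
        (i, j)
        for i, g in enumerate(gold_spans)
        for j, s in enumerate(sys_spans)
        if g[0] < s[1] and s[0] < g[1]
    ]
    best = 0
    for r in range(len(edges), 0, -1):
        for combo in itertools.combinations(edges, r):
            gs = [e[0] for e in combo]
            ss = [e[1] for e in combo]
            if len(set(gs)) == r and len(set(ss)) == r:
                return r
    return best


class TestAlign:
    def test_identity_sets(self):
        spans = [(0, 5), (10, 15)]
        c = align(make_set("gold", spans), make_set("system", spans), "Enzyme")
        assert c.tp_strict == c.tp_lenient == c.detected == c.reference == 2

    def test_partial_overlap_counts_lenient_only(self):
        c = align(
            make_set("gold", [(10, 20)]), make_set("system", [(12, 25)]), "Enzyme"
        )
        assert c.tp_strict == 0 and c.tp_lenient == 1

    def test_mixed_example_from_enumeration(self):
        gold = make_set("gold", [(0, 5), (10, 15), (20, 25), (30, 35)])
        system = make_set("system", [(0, 5), (10, 15), (20, 25), (30, 34), (40, 45)])
        c = align(gold, system, "Enzyme")
        assert (c.tp_strict, c.tp_lenient, c.detected, c.reference) == (3, 4, 5, 4)

    def test_different_documents_rejected(self):
        with pytest.raises(ValueError):
            align(
                make_set("gold", [(0, 5)], doc_id="a"),
                make_set("system", [(0, 5)], doc_id="b"),
                "Enzyme",
            )

    def test_one_to_one_matching_under_lenient(self):
        # one wide system span may only claim one of two gold spans
        gold = make_set("gold", [(0, 5), (6, 12)])
        system = make_set("system", [(0, 12)])
        c = align(gold, system, "Enzyme")
        assert c.tp_lenient == 1

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(0, 40), st.integers(1, 8)), max_size=6),
        st.lists(st.tuples(st.integers(0, 40), st.integers(1, 8)), max_size=6),
    )
    def test_align_equals_brute_force_oracle(self, g_raw, s_raw):
        gold_spans = sorted({(s, s + l) for s, l in g_raw})
        sys_spans = sorted({(s, s + l) for s, l in s_raw})
        c = align(make_set("gold", gold_spans), make_set("system", sys_spans), "Enzyme")
        assert c.tp_lenient == brute_force_max_matching(gold_spans, sys_spans)
        assert c.tp_strict == len(set(gold_spans) & set(sys_spans))


class TestMetrics:
    @pytest.mark.parametrize(
        "tp, detected, reference, p, r, f",
        [
            (3, 5, 4, 0.60, 0.75, 2 * 0.6 * 0.75 / 1.35),
            (4, 5, 4, 0.80, 1.00, 2 * 0.8 / 1.8),
        ],
    )
    def test_hand_calculations(self, tp, detected, reference, p, r, f):
        counts = MatchCounts("Enzyme", tp, tp, detected, reference)
        rep = compute_metrics(counts)
        m = rep.per_type["Enzyme"]["strict"]
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f_measure == pytest.approx(f)

    def test_zero_denominators_degenerate(self):
        rep = compute_metrics(MatchCounts("Enzyme", 0, 0, 0, 0))
        m = rep.per_type["Enzyme"]["strict"]
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)
        assert m.degenerate

    def test_f_is_harmonic_mean_everywhere(self):
        rng = random.Random(3)
        counts = []
        for _ in range(50):
            ref = rng.randint(0, 20)
            det = rng.randint(0, 20)
            tp = rng.randint(0, min(ref, det)) if min(ref, det) else 0
            counts.append(MatchCounts("Enzyme", tp, tp, det, ref))
        rep = compute_metrics(counts)
        for modes in rep.per_type.values():
            for m in modes.values():
                if m.precision + m.recall:
                    assert m.f_measure == pytest.approx(
                        2 * m.precision * m.recall / (m.precision + m.recall)
                    )

    def test_lenient_geq_strict_on_randomized_sets(self):
        rng = random.Random(11)
        for _ in range(1000):
            gold_spans = sorted({(s := rng.randint(0, 60), s + rng.randint(1, 6)) for _ in range(rng.randint(0, 8))})
            sys_spans = sorted({(s := rng.randint(0, 60), s + rng.randint(1, 6)) for _ in range(rng.randint(0, 8))})
            c = align(make_set("gold", gold_spans), make_set("system", sys_spans), "Enzyme")
            rep = compute_metrics(c)
            m = rep.per_type["Enzyme"]
            assert m["lenient"].precision >= m["strict"].precision
            assert m["lenient"].recall >= m["strict"].recall
            assert m["lenient"].f_measure >= m["strict"].f_measure

    def test_self_evaluation_is_perfect(self):
        aset = make_set("gold", [(0, 4), (8, 12)])
        rep = compute_metrics(align(aset, make_set("system", [(0, 4), (8, 12)]), "Enzyme"))
        for m in rep.per_type["Enzyme"].values():
            assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)


class TestCorpusStatistics:
    def test_counts_match_construction(self):
        sets = [
            make_set("gold", [(0, 5), (10, 15)], etype="Enzyme", doc_id="a"),
            make_set("gold", [(0, 5)], etype="Organism", doc_id="b"),
        ]
        stats = corpus_statistics(sets)
        assert stats["Enzyme"] == 2 and stats["Organism"] == 1
        assert stats["pH"] == 0

    def test_empty_corpus_all_zero(self):
        stats = corpus_statistics([])
        assert set(stats.values()) == {0} and len(stats) == 15


class TestInterAnnotatorAgreement:
    def test_identical_sets_give_one(self):
        a = make_set("ann-a", [(0, 4), (8, 12)])
        b = make_set("ann-b", [(0, 4), (8, 12)])
        assert inter_annotator_agreement([a], [b])["strict"] == 1.0

    def test_disjoint_sets_give_zero(self):
        a = make_set("ann-a", [(0, 4)])
        b = make_set("ann-b", [(20, 24)])
        assert inter_annotator_agreement([a], [b])["strict"] == 0.0

    def test_three_shared_one_unique_each(self):
        shared = [(0, 4), (10, 14), (20, 24)]
        a = make_set("ann-a", shared + [(30, 34)])
        b = make_set("ann-b", shared + [(40, 44)])
        assert inter_annotator_agreement([a], [b])["strict"] == pytest.approx(0.75)

    def test_symmetry(self):
        rng = random.Random(5)
        for _ in range(20):
            sa = sorted({(s := rng.randint(0, 50), s + rng.randint(1, 5)) for _ in range(6)})
            sb = sorted({(s := rng.randint(0, 50), s + rng.randint(1, 5)) for _ in range(6)})
            a = make_set("ann-a", sa)
            b = make_set("ann-b", sb)
            ab = inter_annotator_agreement([a], [b])
            ba = inter_annotator_agreement([b], [a])
            assert ab == ba
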