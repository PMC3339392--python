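"""Strict/lenient span-matching evaluation, corpus statistics and agreement.

Precision is the number of correct system annotations divided by the number
of detected annotations; recall divides by the number of reference (gold)
annotations; F is their harmonic mean.  Under strict matching a system
annotation is correct only with an identical span and type; under lenient
matching any character overlap with a same-type reference annotation counts.
Matching is one-to-one: lenient true positives are computed as a maximum
bipartite matching over eligible (gold, system) pairs, so one system span can
never claim two gold spans.

Inter-annotator agreement is the same pairwise F-measure with one annotator
as reference and the other as response (symmetric under one-to-one matching).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .annotations import Annotation, AnnotationSet, ENTITY_LEVELS

__all__ = [
    "MatchCounts",
    "Metrics",
    "EvalReport",
    "align",
    "compute_metrics",
    "corpus_statistics",
    "inter_annotator_agreement",
]


@dataclass
class MatchCounts:
    """True-positive bookkeeping for one entity type (or a pooled aggregate)."""

    etype: str
    tp_strict: int = 0
    tp_lenient: int = 0
    detected: int = 0
    reference: int = 0

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.tp_strict += other.tp_strict
        self.tp_lenient += other.tp_lenient
        self.detected += other.detected
        self.reference += other.reference
        return self

    def validate(self) -> None:
        assert 0 <= self.tp_strict <= self.tp_lenient <= min(self.detected, self.reference)


@dataclass
class Metrics:
    precision: float
    recall: float
    f_measure: float
    degenerate: bool = False

    @classmethod
    def from_counts(cls, tp: int, detected: int, reference: int) -> "Metrics":
        degenerate = detected == 0 or reference == 0
        p = tp / detected if detected else 0.0
        r = tp / reference if reference else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        return cls(p, r, f, degenerate)


@dataclass
class EvalReport:
    """Per-type and micro-averaged strict/lenient P/R/F."""

    per_type: Dict[str, Dict[str, Metrics]] = field(default_factory=dict)
    micro: Dict[str, Metrics] = field(default_factory=dict)
    counts: Dict[str, MatchCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def m(x: Metrics) -> dict:
            return {
                "P": round(x.precision, 6),
                "R": round(x.recall, 6),
                "F": round(x.f_measure, 6),
                "degenerate": x.degenerate,
            }

        return {
            "per_type": {
                t: {mode: m(v) for mode, v in modes.items()}
                for t, modes in sorted(self.per_type.items())
            },
            "micro": {mode: m(v) for mode, v in self.micro.items()},
            "counts": {
                t: {
                    "tp_strict": c.tp_strict,
                    "tp_lenient": c.tp_lenient,
                    "detected": c.detected,
                    "reference": c.reference,
                }
                for t, c in sorted(self.counts.items())
            },
        }

    def to_tsv(self) -> str:
        """Per-type table with strict and lenient R/P/F columns."""
        lines = ["entity\tstrict_R\tstrict_P\tstrict_Fm\tlenient_R\tlenient_P\tlenient_Fm"]
        rows = list(sorted(self.per_type.items())) + [("micro", self.micro)]
        for etype, modes in rows:
            s, l = modes["strict"], modes["lenient"]
            lines.append(
                f"{etype}\t{s.recall:.2f}\t{s.precision:.2f}\t{s.f_measure:.2f}"
                f"\t{l.recall:.2f}\t{l.precision:.2f}\t{l.f_measure:.2f}"
            )
        return "\n".join(lines) + "\n"


def _max_overlap_matching(
    gold: Sequence[Annotation], system: Sequence[Annotation]
) -> int:
    """Size of a maximum one-to-one matching over overlapping same-type pairs."""
    g = nx.Graph()
    left = [("g", i) for i in range(len(gold))]
    g.add_nodes_from(left, bipartite=0)
    g.add_nodes_from((("s", j) for j in range(len(system))), bipartite=1)
    for i, ga in enumerate(gold):
        for j, sa in enumerate(system):
            if ga.span.overlaps(sa.span):
                g.add_edge(("g", i), ("s", j))
    if g.number_of_edges() == 0:
        return 0
    matching = nx.bipartite.maximum_matching(g, top_nodes=left)
    return len(matching) // 2


def align(
    gold: AnnotationSet, system: AnnotationSet, etype: str
) -> MatchCounts:
    """Match one entity type between a gold and a system set on one document.

    Returns counts with both strict (identical span) and lenient (one-to-one
    maximum matching over overlapping spans) true positives.
    """
    if gold.doc_id != system.doc_id:
        raise ValueError(
            f"cannot align sets from different documents: {gold.doc_id!r} vs {system.doc_id!r}"
        )
    g = gold.by_type(etype)
    s = system.by_type(etype)
    g_spans = {(a.span.start, a.span.end) for a in g}
    s_spans = {(a.span.start, a.span.end) for a in s}
    counts = MatchCounts(
        etype=etype,
        tp_strict=len(g_spans & s_spans),
        tp_lenient=_max_overlap_matching(g, s),
        detected=len(s),
        reference=len(g),
    )
    counts.validate()
    return counts


def compute_metrics(
    counts: Iterable[MatchCounts] | MatchCounts,
) -> EvalReport:
    """Turn match counts (possibly pooled over documents) into an EvalReport.

    Counts sharing an etype are summed (micro pooling across documents); the
    overall micro row pools every count.
    """
    if isinstance(counts, MatchCounts):
        counts = [counts]
    by_type: Dict[str, MatchCounts] = {}
    total = MatchCounts(etype="micro")
    for c in counts:
        agg = by_type.setdefault(c.etype, MatchCounts(etype=c.etype))
        agg += c
        total += c
    report = EvalReport(counts=by_type)
    for etype, c in by_type.items():
        report.per_type[etype] = {
            "strict": Metrics.from_counts(c.tp_strict, c.detected, c.reference),
            "lenient": Metrics.from_counts(c.tp_lenient, c.detected, c.reference),
        }
    report.micro = {
        "strict": Metrics.from_counts(total.tp_strict, total.detected, total.reference),
        "lenient": Metrics.from_counts(total.tp_lenient, total.detected, total.reference),
    }
    return report


def corpus_statistics(gold_sets: Iterable[AnnotationSet]) -> Dict[str, int]:
    """Occurrence counts per entity type across a corpus of gold sets."""
    counter: Counter = Counter()
    for aset in gold_sets:
        for ann in aset:
            counter[ann.etype] += 1
    return {etype: counter.get(etype, 0) for etype in sorted(ENTITY_LEVELS)}


def inter_annotator_agreement(
    sets_a: Sequence[AnnotationSet],
    sets_b: Sequence[AnnotationSet],
    etype: Optional[str] = None,
) -> Dict[str, float]:
    """Pairwise F-measure between two annotators over a corpus.

    One annotator is treated as reference, the other as response; with
    one-to-one matching the F-measure is symmetric under swapping.  Returns
    strict and lenient F, pooled over documents (and over types unless one
    etype is given).
    """
    by_doc_b = {s.doc_id: s for s in sets_b}
    all_counts: List[MatchCounts] = []
    for sa in sets_a:
        sb = by_doc_b.get(sa.doc_id)
        if sb is None:
            continue
        types = [etype] if etype else sorted(set(sa.types()) | set(sb.types()))
        for t in types:
            all_counts.append(align(sa, sb, t))
    if not all_counts:
        return {"strict": 0.0, "lenient": 0.0}
    report = compute_metrics(all_counts)
    return {
        "strict": report.micro["strict"].f_measure,
        "lenient": report.micro["lenient"].f_measure,
    }
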