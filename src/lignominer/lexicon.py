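"""Grounding lexicons compiled from TSV tables into longest-match dictionaries.

Two table dialects are supported:

* enzyme tables (BRENDA-style): recommended_name, systematic_name, ec_number,
  synonyms (|-separated), swissprot_ids (|-separated), url;
* taxon tables (NCBI-Taxonomy-style): taxid, scientific_name, rank,
  common_names, synonyms, url;

plus a generic term dialect (name, synonyms, url) for substrate and assay
gazetteers.  Surface forms are tokenized with the pipeline tokenizer and
indexed as case-folded token tuples; short all-uppercase forms (acronyms,
length <= 5) are indexed case-sensitively so that "EG" never fires on "eg".

Matching is longest-match-wins over token sequences, ties broken leftmost,
and never overlapping.
"""

from __future__ import annotations

import logging
import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotations import Span
from .preprocess import Token, tokenize

__all__ = [
    "EnzymeLexiconEntry",
    "TaxonLexiconEntry",
    "TermLexiconEntry",
    "Lexicon",
    "LexiconError",
    "compile_enzyme_lexicon",
    "compile_taxon_lexicon",
    "compile_term_lexicon",
    "match",
    "save_lexicon",
    "load_lexicon",
]

logger = logging.getLogger(__name__)

EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

#: all-caps forms up to this length are matched case-sensitively
ACRONYM_MAX_LEN = 5


class LexiconError(ValueError):
    """Raised for malformed lexicon tables (bad EC syntax, non-integer taxid...)."""


@dataclass(frozen=True)
class EnzymeLexiconEntry:
    recommended_name: str
    systematic_name: str
    ec_number: str
    synonyms: Tuple[str, ...] = ()
    swissprot_ids: Tuple[str, ...] = ()
    url: str = ""

    def surfaces(self) -> List[str]:
        return [self.recommended_name] + (
            [self.systematic_name] if self.systematic_name else []
        ) + list(self.synonyms)


@dataclass(frozen=True)
class TaxonLexiconEntry:
    taxid: int
    scientific_name: str
    rank: str = ""
    common_names: Tuple[str, ...] = ()
    synonyms: Tuple[str, ...] = ()
    url: str = ""

    def surfaces(self) -> List[str]:
        return [self.scientific_name] + list(self.common_names) + list(self.synonyms)


@dataclass(frozen=True)
class TermLexiconEntry:
    name: str
    synonyms: Tuple[str, ...] = ()
    url: str = ""

    def surfaces(self) -> List[str]:
        return [self.name] + list(self.synonyms)


def _is_acronym(surface: str) -> bool:
    return (
        len(surface) <= ACRONYM_MAX_LEN
        and surface.isupper()
        and any(c.isalpha() for c in surface)
    )


@dataclass
class Lexicon:
    """Compiled longest-match dictionary over case-folded token tuples."""

    kind: str
    entries: List[object] = field(default_factory=list)
    _folded: Dict[Tuple[str, ...], List[int]] = field(default_factory=dict)
    _exact: Dict[Tuple[str, ...], List[int]] = field(default_factory=dict)
    max_tokens: int = 0

    def add_surface(self, surface: str, entry_index: int) -> None:
        surface = surface.strip()
        if not surface:
            return
        toks = tokenize(surface)
        if not toks:
            return
        if _is_acronym(surface):
            key = tuple(t.surface for t in toks)
            self._exact.setdefault(key, [])
            if entry_index not in self._exact[key]:
                self._exact[key].append(entry_index)
        else:
            key = tuple(t.lower for t in toks)
            self._folded.setdefault(key, [])
            if entry_index not in self._folded[key]:
                self._folded[key].append(entry_index)
        self.max_tokens = max(self.max_tokens, len(toks))

    def lookup_tokens(self, toks: Sequence[Token]) -> List[object]:
        """Entries whose surface form equals this token sequence."""
        hits: List[int] = []
        hits += self._folded.get(tuple(t.lower for t in toks), [])
        hits += self._exact.get(tuple(t.surface for t in toks), [])
        seen, out = set(), []
        for i in hits:
            if i not in seen:
                seen.add(i)
                out.append(self.entries[i])
        return out

    def lookup_surface(self, surface: str) -> List[object]:
        """Entries matching a raw string (tokenized the same way as documents)."""
        return self.lookup_tokens(tokenize(surface))

    @property
    def n_surfaces(self) -> int:
        return len(self._folded) + len(self._exact)

    def genus_names(self) -> frozenset:
        """Case-folded genus vocabulary (taxon lexicons only): single-word
        scientific names plus first words of binomials."""
        names = set()
        for e in self.entries:
            if isinstance(e, TaxonLexiconEntry):
                parts = e.scientific_name.split()
                if len(parts) == 1:
                    names.add(parts[0].casefold())
                elif len(parts) >= 2 and parts[0][0].isupper():
                    names.add(parts[0].casefold())
        return frozenset(names)


def _split_multi(cell: str) -> Tuple[str, ...]:
    return tuple(s.strip() for s in str(cell).split("|") if s.strip())


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("empty lexicon table: %s", path)
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LexiconError(f"{path}: missing columns {missing}")
    return df


def compile_enzyme_lexicon(table_path) -> Lexicon:
    """Compile a BRENDA-style enzyme table into a grounding lexicon."""
    df = _read_table(
        table_path,
        ["recommended_name", "systematic_name", "ec_number", "synonyms", "swissprot_ids", "url"],
    )
    lex = Lexicon(kind="enzyme")
    for row_num, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        ec = row.ec_number.strip()
        if not EC_RE.match(ec):
            raise LexiconError(f"{table_path}: row {row_num}: bad EC number {ec!r}")
        if not row.recommended_name.strip():
            raise LexiconError(f"{table_path}: row {row_num}: empty recommended_name")
        entry = EnzymeLexiconEntry(
            recommended_name=row.recommended_name.strip(),
            systematic_name=row.systematic_name.strip(),
            ec_number=ec,
            synonyms=_split_multi(row.synonyms),
            swissprot_ids=_split_multi(row.swissprot_ids),
            url=row.url.strip(),
        )
        idx = len(lex.entries)
        lex.entries.append(entry)
        for surface in entry.surfaces():
            lex.add_surface(surface, idx)
    if not lex.entries:
        logger.warning("enzyme lexicon %s compiled with zero entries", table_path)
    return lex


def compile_taxon_lexicon(table_path) -> Lexicon:
    """Compile an NCBI-Taxonomy-style table into a grounding lexicon."""
    df = _read_table(
        table_path, ["taxid", "scientific_name", "rank", "common_names", "synonyms", "url"]
    )
    lex = Lexicon(kind="taxon")
    seen_names = set()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            taxid = int(row.taxid)
        except (TypeError, ValueError):
            raise LexiconError(f"{table_path}: row {row_num}: non-integer taxid {row.taxid!r}")
        if taxid <= 0:
            raise LexiconError(f"{table_path}: row {row_num}: taxid must be positive")
        sci = row.scientific_name.strip()
        if not sci:
            raise LexiconError(f"{table_path}: row {row_num}: empty scientific_name")
        if sci in seen_names:
            raise LexiconError(f"{table_path}: row {row_num}: duplicate scientific_name {sci!r}")
        seen_names.add(sci)
        entry = TaxonLexiconEntry(
            taxid=taxid,
            scientific_name=sci,
            rank=row.rank.strip(),
            common_names=_split_multi(row.common_names),
            synonyms=_split_multi(row.synonyms),
            url=row.url.strip(),
        )
        idx = len(lex.entries)
        lex.entries.append(entry)
        for surface in entry.surfaces():
            lex.add_surface(surface, idx)
    return lex


def compile_term_lexicon(table_path, kind: str = "term") -> Lexicon:
    """Compile a generic gazetteer table (name, synonyms, url)."""
    df = _read_table(table_path, ["name"])
    lex = Lexicon(kind=kind)
    for row in df.itertuples(index=False):
        name = row.name.strip()
        if not name:
            continue
        entry = TermLexiconEntry(
            name=name,
            synonyms=_split_multi(getattr(row, "synonyms", "")),
            url=str(getattr(row, "url", "")).strip(),
        )
        idx = len(lex.entries)
        lex.entries.append(entry)
        for surface in entry.surfaces():
            lex.add_surface(surface, idx)
    return lex


def match(tokens: Sequence[Token], lexicon: Lexicon) -> List[Tuple[Span, List[object]]]:
    """Longest-match gazetteer tagging over a token sequence.

    All matching token n-grams are enumerated, then overlaps are resolved
    longest-first (character length), ties leftmost.  Returns non-overlapping
    ``(span, entries)`` pairs in document order.
    """
    if not lexicon.entries or not tokens:
        return []
    candidates: List[Tuple[Span, List[object]]] = []
    n = len(tokens)
    for i in range(n):
        for width in range(min(lexicon.max_tokens, n - i), 0, -1):
            seq = tokens[i : i + width]
            entries = lexicon.lookup_tokens(seq)
            if entries:
                candidates.append((Span(seq[0].span.start, seq[-1].span.end), entries))
    candidates.sort(key=lambda c: (-(len(c[0])), c[0].start))
    accepted: List[Tuple[Span, List[object]]] = []
    for span, entries in candidates:
        if not any(span.overlaps(a[0]) for a in accepted):
            accepted.append((span, entries))
    accepted.sort(key=lambda c: c[0].start)
    return accepted


def save_lexicon(lexicon: Lexicon, path) -> None:
    """Persist a compiled lexicon (pickle)."""
    Path(path).write_bytes(pickle.dumps(lexicon))


def load_lexicon(path) -> Lexicon:
    """Load a lexicon previously written by :func:`save_lexicon`."""
    obj = pickle.loads(Path(path).read_bytes())
    if not isinstance(obj, Lexicon):
        raise LexiconError(f"{path}: not a compiled lexicon")
    return obj
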