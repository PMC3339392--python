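"""Ligature normalization, enzyme-aware tokenization and sentence splitting.

PDF-extracted article text frequently carries typographic ligatures
(U+FB00..U+FB06) that break dictionary matching ("puriﬁed" vs "purified");
these are expanded to their constituent ASCII characters first, with an
offset map back to the original text.

The tokenizer is deliberately simple — words, numbers, punctuation, symbols —
but enzyme-aware: hyphenated chemical and enzyme names ("alpha-galactosidase",
"Bio-Gel") stay single word tokens, decimal and space-grouped numbers
("43.33", "27 000") stay whole, and "°C" is one symbol token.

The sentence splitter is a small rule cascade over the token stream that
refuses to split after known abbreviations ("sp.", "et al.", "Fig.", single
uppercase initials) or when the next token is lowercase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .annotations import Span
from .resources import load_list

__all__ = [
    "Token",
    "SentenceSpan",
    "LIGATURES",
    "normalize_ligatures",
    "tokenize",
    "split_sentences",
    "preprocess",
]

#: Unicode ligature codepoint -> ASCII expansion.
LIGATURES = {
    "ﬀ": "ff",
    "ﬁ": "fi",
    "ﬂ": "fl",
    "ﬃ": "ffi",
    "ﬄ": "ffl",
    "ﬅ": "st",  # U+FB05 LATIN SMALL LIGATURE LONG S T
    "ﬆ": "st",
}


@dataclass(frozen=True)
class Token:
    """One token: its span in the text, coarse kind, and case-folded surface."""

    span: Span
    kind: str  # word | number | punctuation | symbol
    surface: str

    @property
    def lower(self) -> str:
        return self.surface.casefold()


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence extent (first token start to last token end) and its ordinal."""

    span: Span
    index: int


def normalize_ligatures(text: str) -> Tuple[str, List[int]]:
    """Expand ligature codepoints; return (normalized_text, offset_map).

    ``offset_map[i]`` is the index in the *original* text of the character
    that produced normalized character ``i``.  Idempotent: the output
    contains no ligature codepoints.
    """
    out: List[str] = []
    offset_map: List[int] = []
    for i, ch in enumerate(text):
        repl = LIGATURES.get(ch)
        if repl is None:
            out.append(ch)
            offset_map.append(i)
        else:
            for c in repl:
                out.append(c)
                offset_map.append(i)
    return "".join(out), offset_map


# Order matters: space-grouped thousands and decimals before bare integers;
# words allow internal hyphens only when the continuation contains a letter
# (keeps "alpha-galactosidase" whole but leaves "A-0.5" as "A" + "-" + "0.5").
_TOKEN_RE = re.compile(
    r"""
    (?P<number>\d{1,3}(?:[\ \u00A0]\d{3})+(?!\d)
              |\d+\.\d+
              |\d+)
    |(?P<word>[A-Za-z][A-Za-z0-9']*(?:-(?=[A-Za-z0-9',]*[A-Za-z])[A-Za-z0-9',]*[A-Za-z0-9])*)
    |(?P<symbol>°\ ?C\b|[°%±×≥≤~])
    |(?P<punct>[^\sA-Za-z0-9])
    """,
    re.VERBOSE,
)


def tokenize(text: str) -> List[Token]:
    """Split text into word / number / punctuation / symbol tokens."""
    tokens: List[Token] = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "punct":
            kind = "punctuation"
        tokens.append(Token(Span(m.start(), m.end()), kind, m.group()))
    return tokens


_TERMINALS = {".", "!", "?"}


def _load_abbreviations(extra: Optional[Sequence[str]] = None) -> frozenset:
    abbrevs = set(load_list("lists/sentence_abbreviations.txt"))
    if extra:
        abbrevs.update(extra)
    return frozenset(a.casefold() for a in abbrevs)


def split_sentences(
    text: str,
    tokens: Sequence[Token],
    abbreviations: Optional[Sequence[str]] = None,
) -> List[SentenceSpan]:
    """Segment a tokenized text into sentences.

    A period ends a sentence unless the preceding token is a known
    abbreviation or a single uppercase initial, or the following token starts
    lowercase.  "!" and "?" always end a sentence.  Decimals never split
    (the tokenizer keeps them whole).
    """
    if not tokens:
        return []
    abbrevs = _load_abbreviations(abbreviations)
    sentences: List[SentenceSpan] = []
    start_idx = 0
    for i, tok in enumerate(tokens):
        if tok.kind != "punctuation" or tok.surface not in _TERMINALS:
            continue
        is_last = i == len(tokens) - 1
        if tok.surface == "." and not is_last:
            prev = tokens[i - 1] if i > start_idx else None
            nxt = tokens[i + 1]
            if prev is not None and prev.kind == "word":
                if prev.lower in abbrevs:
                    continue
                if len(prev.surface) == 1 and prev.surface.isupper():
                    continue  # initials: "E. coli", "M. incrassata"
            first = nxt.surface[0]
            if first.islower():
                continue
            if nxt.kind not in ("word", "number") and first not in "\"'(“[":
                continue
        sentences.append(
            SentenceSpan(Span(tokens[start_idx].span.start, tok.span.end), len(sentences))
        )
        start_idx = i + 1
    if start_idx < len(tokens):
        sentences.append(
            SentenceSpan(
                Span(tokens[start_idx].span.start, tokens[-1].span.end), len(sentences)
            )
        )
    return sentences


def preprocess(text: str):
    """Normalize ligatures, tokenize and sentence-split in one call.

    Returns ``(normalized_text, offset_map, tokens, sentences)``; all spans
    index the normalized text.
    """
    norm, offset_map = normalize_ligatures(text)
    tokens = tokenize(norm)
    sentences = split_sentences(norm, tokens)
    return norm, offset_map, tokens, sentences
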