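# Methods

This note documents the models, rules and parameters behind lignominer, the
design choices made where the design was genuinely open, and what the test
suite does and does not demonstrate about real literature.

## Problem setting

Enzyme-characterization papers report, in highly stereotyped prose, the facts
a curated database of characterized lignocellulose-active proteins needs:
enzyme identity, source organism and strain, expression host, assay methods,
substrates, and experimentally determined catalytic properties. The package
extracts these as typed character spans (standoff annotations) over the
article text and, where possible, grounds them in external nomenclatures: EC
numbers for enzymes, taxonomy identifiers for organisms. Everything is
rule-based — gazetteers, morphological rules, cue vocabularies — because the
target phrasing is conventionalized enough that transparent, editable rules
cover it, and because every decision can then be traced to a rule or a
lexicon row.

## Coordinate system

All offsets are 0-based, half-open character indices into the
ligature-normalized text. Ligature expansion (U+FB00..U+FB06 to their ASCII
constituents) runs before any other stage because PDF extraction routinely
yields "puriﬁed" for "purified", which silently defeats dictionary matching.
An offset map back to the raw text is kept so spans can be projected onto the
original bytes. Normalization is idempotent; gold annotations are interpreted
in the normalized coordinate system.

## Tokenization and sentence splitting

Tokens are words, numbers, punctuation and symbols. Three domain-driven
choices: a hyphen joins word characters into one token only when the
continuation contains a letter (keeps "alpha-galactosidase" and "Bio-Gel"
whole while leaving "A-0.5" as three tokens so the decimal survives);
space-grouped thousands ("27 000") are a single number token because
molecular weights are printed that way; "°C" is one symbol token, which keeps
the temperature grammar trivial. Part-of-speech tagging is deliberately
omitted: no downstream rule needs it, and dropping it removes a model
dependency.

Sentence boundaries are periods/!/? filtered by a small rule cascade: no
split after entries of an editable abbreviation list ("sp.", "spp.", "et",
"al.", "Fig.", ...), after single uppercase initials ("E. coli",
"M. incrassata"), or when the next token starts lowercase. The abbreviation
list ships as a data file because no fixed list survives contact with a new
corpus.

## Lexicons and matching

Enzyme tables follow a BRENDA-style TSV dialect (recommended name, systematic
name, EC number, |-separated synonyms and SwissProt ids, URL); organism
tables follow an NCBI-Taxonomy-style dialect (taxid, scientific name, rank,
common names, synonyms, URL); substrates and assays use a generic term
dialect. The bundled tables are small curated fixtures (~45 enzymes with
real EC nomenclature, ~40 taxa, ~25 substrates, ~10 assays) — large enough to
exercise every code path, small enough to audit by eye. Full database dumps
in the same dialects are supported but never required.

Surface forms are tokenized exactly like documents and indexed as case-folded
token tuples. All-uppercase forms of length <= 5 are indexed case-sensitively
(acronym heuristic): without it, a synonym like "CDH" would fire on ordinary
lowercase text. Matching enumerates token n-grams and resolves overlaps
longest-first (character length), ties leftmost, never overlapping — verified
in tests against a brute-force all-substring oracle. EC numbers are validated
as `d.d.d.(d|-)`; a surface form shared by entries with different EC numbers
is retained for both and flagged ambiguous at grounding time.

## Enzyme recognition

Detection is the union of gazetteer matches and a morphological rule: word
tokens ending in "-ase"/"-ases" with a stem of at least 4 characters, minus
an editable stoplist of common English false friends (disease, increase,
release, database, ...). Gazetteer matches win on overlap. The stem-length
floor of 4 removes "base"/"case"/"phase" without a stoplist entry; genuinely
short enzyme names (e.g. "lipase") are carried by the gazetteer instead.

Author-coined abbreviations are document-local and absent from nomenclature
resources, so the pipeline records definitions of the shape
`<enzyme mention> ( <short form> )` where the short form is one token of 1-10
characters, contains no digit (rejecting "(Fig. 2)"), is shorter than its
long form, and passes an in-order letter-subsequence check against the long
form ignoring case and hyphens (a Schwartz–Hearst-style validation: E,G occur
in order in "endoglucanase"). Coreference is forward-only from the defining
occurrence: later standalone occurrences of the short form (matched
case-sensitively) become Enzyme annotations that copy the antecedent's
grounding and record the antecedent span. If a short form is redefined, the
later definition shadows the earlier one from its position onward.
Forward-only scope is the conservative reading of document-local coreference;
pre-definition uses are rare and risky to link.

Grounding looks the mention surface (or the antecedent surface, for
abbreviation-derived mentions) up in the lexicon, stripping a terminal plural
"s" on a failed lookup. Misses remain as ungrounded candidates with
provenance "suffix_rule" — they are real recall on novel enzymes at a small
precision cost, which the closed-loop test quantifies. An audit hook reports
what fraction of gold-enzyme false negatives look like abbreviations (short,
spaceless, containing capitals), since abbreviation handling is the dominant
known failure mode of this family of pipelines.

## Organism recognition

Four detectors, in priority order: taxonomy-lexicon hits (longest match);
the binomial grammar — a capitalized token in the genus vocabulary (genus
rows plus first words of binomial rows) followed by a lowercase alphabetic
epithet of >= 4 characters that is not in a function-word stop set; a longer
grammar span supersedes a bare-genus lexicon hit nested inside it;
abbreviated binomials "X. epithet" expanded via the document's genus sharing
that initial (unresolvable ones are kept but flagged); and "Genus sp."/
"spp." spans (including the trailing period). Generic group mentions — an
adjective followed by fungus/fungi/yeast/bacteria/... — sit behind a config
flag, default on, because curators annotate them even though they cannot be
grounded below a very coarse rank. A blocklist of fixed phrases suppresses
organism words inside expressions like "bovine serum albumin".

Normalization maps every mention to a scientific name (binomial or genus);
grounding attaches taxid, rank and URL when the normalized name is in the
lexicon, and leaves spelling variants ("Trichoderma viridie") ungrounded and
flagged rather than guessing. Strains are alphanumeric designators
(letter(s)+digits, or a 2-6-letter collection prefix followed by a number)
immediately after an organism mention or after "strain"/"isolate", and are
linked to the nearest preceding organism. Hosts are organism mentions whose
start lies within 25 characters after an expression cue ("expressed in",
"produced in", "host", ...) in the same sentence; the proximity bound keeps
the source organism in the same sentence from being swept up. Every Host
span coincides with an Organism span by construction.

The machine-learning components of hybrid organism taggers are intentionally
not reproduced: the behaviors that matter here (scientific-name detection,
normalization, grounding, strains) are fully specified by rules, and the
documented failure modes of the hybrid systems are rule-addressable.

## Quantities and sentence contexts

Quantity patterns are applied to each sentence in priority order — pH,
temperature, specific activity, percent, molar — with consumed character
ranges masked from later patterns, so "pH 5.0" never also yields a bare
number. pH ranges accept "pH N and M"/"pH N to M" only when M > N and M is
not itself a unit-bearing value (the lookahead rejects "pH 5.0 and 55°C");
descending pairs fall back to two independent mentions. pH values outside
[0, 14] are kept but flagged implausible. Molarity is case-sensitive ("0.1 M"
yes, "A-0.5 m" no). Values are stored both as floats and as the exact
printed numeral, so serialized features are canonical strings ("55", "5.0",
"43.33").

Sentence classification combines quantities with editable cue vocabularies:
Temperature and pH require a quantity of their kind plus an
activity/stability cue; SpecificActivity requires a U/mg quantity;
KineticAssayConditions requires a kinetic cue (Km, kcat, Michaelis, ...) plus
a condition quantity; ActivityAssayConditions an assay-condition cue (assay,
buffer, reaction mixture, ...) plus a condition quantity; Glycosylation a
glycosylation morpheme (prefix-matched, so "glycosyl*" covers
"N-glycosylated"); SubstrateSpecificity a specificity cue plus a Substrate or
Enzyme mention in the sentence; ProductAnalysis a product/identification cue.
A sentence may carry several types — kinetic and activity conditions share
phrasing, and no exclusivity is imposed.

The optimum of a Temperature/pH context is the first quantity of the
matching kind after an optimum cue ("maximum/optimal ... at/of/was");
stability-only sentences therefore have none, and the optimum always belongs
to the sentence's own quantity list. Profile pairs associate each percentage
with the nearest following condition quantity before the next percentage; a
single percentage distributes over coordinated conditions joined by
"and (also) (at)" — "retained 80% activity at pH 3.0 and also at pH 8.0"
yields (3.0, 80) and (8.0, 80). Unpaired percentages are logged and dropped.

Gene detection requires both the gene-symbol shape (lowercase-initial, 3-8
alphanumerics, at least one digit) and adjacency (within two word tokens) to
a cue ("gene", "encoding", ...). The shape alone was considered and
rejected: it is indistinguishable from strain designators and catalogue
numbers, and the cue-anchored rule covers how characterization papers
actually introduce gene names.

## Ontology export

Each document populates an ABox under a fixed schema (shipped as Turtle):
one individual per distinct normalized key — enzymes keyed by EC number with
surface fallback, organisms by taxid with normalized-name fallback — so
surface variants collapse onto one individual with mention-level provenance
(sentence individuals carrying character offsets). Relations: fromOrganism
links each enzyme to the nearest preceding organism mention (falling back to
the document's most frequent organism — a heuristic chosen because
characterization papers overwhelmingly describe one source organism);
hasOptimalTemperature/hasOptimalPH/hasSpecificActivity attach extracted
values to the nearest preceding enzyme; encodes links a gene to an enzyme in
the same "encod*" sentence; hasStrain follows the strain-organism link. URIs
are hash-style with percent-encoded normalized keys, stable across runs.
Serialization supports Turtle and RDF/XML; round-trips are isomorphic and
repeated serialization is byte-identical. No reasoning or SPARQL service is
provided.

## Evaluation

Precision = correct detections / all detections; recall = correct
detections / reference annotations; F is their harmonic mean. Strict
correctness means identical span and type; lenient means any character
overlap with a same-type reference annotation. Matching is one-to-one via
maximum bipartite matching (Hopcroft–Karp), so a single wide system span
cannot claim two gold spans under lenient scoring — the main way naive
overlap counting inflates scores. Zero denominators yield 0 with a
degenerate flag. Micro-averaging pools counts across documents (and types,
for the overall row) before dividing. Inter-annotator agreement is the same
pairwise F with one annotator as reference; under one-to-one matching it is
symmetric, which the tests verify. Features (grounding, normalized values)
are excluded from the match criterion — span and type only — matching how
such corpora are scored.

The evaluator is tested three ways: against a brute-force enumeration of all
injective pairings on sets of up to ~10 annotations; against the corruption
ledger (below); and for the lenient >= strict invariant on 1,000 randomized
set pairs.

## Synthetic corpus

The generator assembles articles from parameterized sentence templates that
mirror characterization prose: purification with an author abbreviation,
abbreviation reuse with specific activity, temperature optimum with a
relative-activity profile, pH optimum, a stability sentence without an
optimum, kinetic conditions, gene + expression host, "Genus sp. F75" with a
substrate, substrate specificity, abbreviated genus reuse, an assay sentence,
glycosylation and product-analysis sentences, plus distractors: the "bovine
serum albumin" phrase, filler prose salted with -ase stoplist words, and (in
every fourth document) a novel "-ase" coinage that only the suffix rule can
see and that gold deliberately omits. Defaults are 20 documents with 10
enzyme, 4 organism, 3 substrate and 1 assay mention(s) per document — sized
like short characterization papers and generated in seconds on one CPU.
Every inserted entity is recorded as gold with exact offsets; generation is
byte-deterministic per seed.

`corrupt_annotations` degrades a gold set with per-annotation drop,
boundary-shift (1-3 characters, still overlapping the source, never exactly
matching it, never touching another same-type gold span) and spurious
injection (never overlapping same-type gold), emitting a ledger of realized
counts. By construction strict true positives equal `kept_exact` and lenient
true positives equal `kept_exact + shifted`, which makes the ledger an exact
oracle for the evaluator.

What the closed-loop test shows: on an uncorrupted generated corpus the
pipeline reaches strict recall 1.0 for Enzyme, Organism, Substrate and Assay
with strict precision >= 0.95 (the -ase coinages are the only tolerated false
positives). What it does not show: performance on real articles, whose
spelling variants, layout artifacts, non-templated phrasing and sub-sentence
gold spans the generator does not emulate. Published pipelines of this
family score roughly 0.7-0.9 F on real gold corpora; the closed loop is a
correctness check on the machinery, not a performance claim.

## Numerical and degenerate-input choices

- Duplicate (type, span) annotations merge silently; duplicates would break
  evaluation counts.
- Empty lexicon tables compile to empty matchers with a logged warning;
  malformed rows (bad EC syntax, non-integer taxid) fail with the row number.
- Empty documents annotate to empty sets; an empty token stream yields no
  sentences.
- Sentence-level annotations span whole sentences (first token start to
  terminal punctuation); gold in the bundled generator uses the same
  convention. Sub-sentence condition clauses are a known representational
  limitation.
- The standoff writer sorts sets, annotations and feature keys, so output is
  byte-deterministic.

## Known limitations

- Grounding is exact-match (plus plural stripping); no fuzzy matching, so
  spelling variants stay ungrounded by design.
- Abbreviation coreference requires the parenthesized definition pattern;
  acronyms introduced without parentheses are missed.
- The fromOrganism and optimum-to-enzyme attachment heuristics
  (nearest-preceding, most-frequent fallback) are document-level
  approximations; multi-enzyme comparison papers will mis-attach some
  relations.
- Cue vocabularies are seed lists, editable but not exhaustive; recall on
  real corpora depends on extending them.
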