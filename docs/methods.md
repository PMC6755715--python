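# Methods

## Problem and approach

`lexner` performs dictionary-lookup named-entity recognition and linking:
every mention of a term from a user-supplied vocabulary is located in free
text with exact character offsets and, when a term→URI table is available,
linked to an ontology class. The design premise is minimalism — a flat term
list is far easier to obtain than a training corpus, and for well-delimited
vocabularies (chemical compounds, phenotypes, diseases) exact lookup remains
competitive. Only direct matches are found: lexical variants must be added
to the lexicon; there is no stemming, fuzzy matching, or semantic expansion.

## Normalization

Both lexicon terms (once, offline) and input text (per request) are
rewritten by one total, idempotent function: lowercase; map every
whitespace character to a space; within each token, drop non-alphanumeric
characters at the edges and replace non-alphanumeric characters in the
interior with `.`; collapse/strip spaces. "Alphanumeric" follows Unicode
letter/digit semantics, so `α` is a letter and multi-byte text is safe.

The resulting alphabet (lowercase alphanumerics, single spaces, interior
`.`) is closed under the function, which gives two properties the rest of
the pipeline depends on: compiled index entries are fixed points, so
re-normalizing is harmless, and the links table can normalize its keys with
the same function and be queried with either raw or normalized terms.
Dropping *edge* punctuation (the full stop of "E. coli", a trailing comma)
while wildcarding *interior* punctuation ("acid-adenine" → `acid.adenine`)
is what makes idempotence possible at all: a variant that wildcards edge
punctuation too would turn `a-b` into `a.b` on the first pass and `ab` on
the second. Tokens left with no alphanumeric character (bare punctuation)
are removed; lexicon terms that vanish entirely are dropped with a warning.

## The four-part index

Compilation normalizes, deduplicates, and partitions terms by word count:
`one_word`, `two_word`, `more_words` (3+, sorted), plus `first_two_words`,
the set of two-word prefixes of the 3+-word terms. The partition is
complete (part sizes sum to the number of distinct normalized terms) and is
serialized as four plain-text files (`<name>_word1.txt`, `_word2.txt`,
`_words.txt`, `_words2.txt`), one term per line, with `<name>_links.tsv`
alongside when links exist; loading is the exact inverse of saving.

Links tables are sorted by (term, URI) — the order a plain line sort of the
two-column file produces — and lookup returns the first entry for a term,
so duplicate labels across classes resolve deterministically.

An OWL/RDF-XML ontology can stand in for both inputs: labels and
exact/related synonyms of every `owl:Class` with its own URI become terms
linked to that class. Broad/narrow synonyms are deliberately not harvested,
and anonymous classes are skipped with a warning.

## Inverted recognition

The recognizer inverts the usual lookup direction: the (normalized,
content-filtered) input text contributes the patterns, the lexicon is the
searched corpus. Content filtering removes stop-words and words shorter
than `min_entity_length` (default 3 — two-character tokens are mostly
spurious acronym hits). Two pattern sets are built: all content words, and
all consecutive content-word pairs. Three matching jobs follow:

1. words vs. `one_word` entries;
2. pairs (joined by a space) vs. `two_word` entries;
3. pairs vs. `first_two_words`; terms behind a matched prefix become
   *candidates*.

Index-time matching is whole-entry and position-wise: a `.` on the text
side (a normalized special character) matches any entry character, while a
`.` on the entry side must be met by a `.` in the pattern; lengths and
spaces must align. The asymmetry mirrors using text words as search
patterns over term files.

Matched terms are then located in the **original** text, which serves two
purposes: recovering exact offsets (0-based, end-exclusive, counted in
Unicode characters, never bytes) and filtering artifacts of the processed
text — pairs glued together by stop-word removal, wildcard pattern words,
and 3+-word candidates nominated only by prefix. Location is
case-insensitive; a term's `.` matches any single non-whitespace character;
each single space in a term matches a run of whitespace and/or full stops
(so terms survive the removal of abbreviation dots); both match boundaries
must not touch a letter or digit; and the surface span must itself reach
`min_entity_length`. Gaps resolve greedily (longest first, with
backtracking), realized by stdlib regular expressions compiled per term and
anchored at every candidate start. Output keeps partial overlaps (a short
term inside a longer one), collapses exact duplicates (same term, same
span), and sorts by (start, end, term) — the output order is otherwise
unspecified, so a deterministic tie-break is pinned here.

Consequences worth knowing: a two-word pattern spanning a removed stop-word
is allowed at match time and reliably discarded at resolution; a term equal
to a stop-word can never be annotated, because it never enters the
patterns; and the score of a mention uses the character length of the
annotated *surface* span (including internal spaces and punctuation
absorbed by gaps), since the score describes the concrete mention rather
than the abstract term.

## Scoring and output

`score(nc) = 1 − 1/ln(nc)` with `nc = end − start`; strictly increasing,
always < 1, 0.08976 at the minimum length 3. Scores are printed at 5
decimals (Python's round-half-even formatting). Plain TSV rows are
`start, end, surface[, uri]`; BeCalm TSV rows are `document_id, section,
start, end, score, surface, entity_type, uri-or-empty` — the dialect's
column order is pinned by golden tests. In multi-lexicon mode the lexicon
name is the entity type; terms present in ≥ 2 lexicons are reported once
under `Unknown` with no URI, since the competing lexicons may link the same
string differently.

## Estimator surface

`EntityRecognizer` wraps compile/annotate in the scikit-learn contract:
hyper-parameters (`min_entity_length`, `stopwords`, `entity_type`, `name`)
in the constructor, `fit(terms, links=...)` building `lexicon_`, `links_`,
`n_terms_`, `annotate(text)` for one document, `transform`/`predict` for
batches, plus `save`/`load` for the four-file layout. `get_params`,
`set_params`, and `clone` behave as usual.

## Synthetic corpora and the oracle

The generator plants a known number of mentions into filler text and
records their exact offsets. Terms have 1–5 words, every word ≥ 3
lowercase letters and not a stop-word, with occasional interior special
characters (future wildcards); fillers include genuine stop-words.
Decorations apply only transformations the matching contract is specified
to survive — case flips, widened gaps (extra spaces, `. `), substitution of
one special character for another — and never touch an alphanumeric
character. Mentions are always delimited by non-alphanumeric separators,
and no separator other than a full stop is glued onto a mention: a glued
comma changes the adjacent token and, by design of the exact index match,
hides the term (full stops are the one punctuation normalization removes at
token edges). Under `decoration_level="none"` recall of planted mentions is
exactly 1.0 by construction, and the suite asserts it.

`naive_recognize` is the independent correctness oracle: per-term
exhaustive scanning with a recursive character matcher (longest-gap-first,
the same greedy semantics as the production regexes) and the same
mentioned-term conditions, but none of the index machinery — no four-part
split, no prefix staging, no pattern sets shared with the fast path. The
suite asserts set-equality of (start, end, term) between recognizer and
oracle on 500 seeded corpora spanning all decoration levels (and more in
unit tests); corpora are small (6 terms, 6 mentions, a few hundred
characters), which keeps the full property suite under a few seconds while
exercising 1/2/3+-word terms, wildcards, and stop-word boundaries.

What the synthetic corpora do *not* emulate: real biomedical prose
(sentence structure, nested terminology, ambiguous abbreviations), lexicon
scale (millions of terms), or annotation-server load. Passing tests
therefore demonstrate contract correctness, not corpus-level accuracy;
`scripts/evaluate_corpus.py` exists for users who can supply a real
gold-standard corpus locally.

## Numerical and degenerate-input choices

- Offsets are Unicode character counts; no byte arithmetic anywhere.
- `score` raises for `nc < 2` (ln ≤ 0); recognized spans can never get
  there because of the length floor.
- Empty text, stop-word-only text, and absent terms yield empty results,
  not errors; an empty lexicon (after cleanup) is an error at compile time.
- Ties in output order are broken by (start, end, term); links ties by
  (term, uri) with first-match lookup.
- The per-term location regex is cached (LRU, 4096 entries) since lexicons
  are reused across documents.

## Known limitations

- Surfaces containing a tab or newline (a gap can absorb them) break the
  single-line TSV output formats; the library result is unaffected.
- Linking is exact-string only; a term appearing in several ontologies
  resolves to whichever entry sorts first.
- The interior-wildcard normalization means an interior literal full stop
  (rare in practice) behaves as a wildcard rather than being removed.
- Recognition cost is O(text length × matched terms) at the resolution
  step; the index keeps the *matching* step small, but pathological texts
  matching thousands of terms will spend time in resolution.
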