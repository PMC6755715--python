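"""Online inverted recognition and exact offset resolution.

Instead of searching every lexicon term in the text, the words of the
(normalized, content-filtered) input text are used as patterns against the
compiled lexicon — far fewer patterns when the lexicon is large.  Three
matching jobs run over the four-part index:

1. one-word job: every content word against the one-word part;
2. two-word job: every consecutive content-word pair against the two-word
   part;
3. more-words job: the pairs against the first-two-words prefix part, and
   terms behind a matched prefix become *candidates*.

Because the filtered text can glue together words that were never adjacent in
the original, and candidates are only known by prefix, every matched term is
then located in the *original* text; terms with no occurrence are dropped.
Offsets are 0-based, end-exclusive, counted in Unicode characters.

Wildcard semantics are asymmetric by construction.  At index-matching time
the text is the pattern: a ``.`` in a text word (a normalized special
character) matches any character of a lexicon entry, while a ``.`` in an
entry must be matched by a ``.`` in the pattern.  At offset-resolution time
the term is the pattern: a ``.`` in the term matches any single
non-whitespace character of the original text, and each single space in the
term matches a run of whitespace and/or full stops (so terms survive the
removal of full stops from abbreviations).  Matches are case-insensitive and
must not butt directly against a letter or digit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

from .lexicon import CompiledLexicon, LinksTable
from .linking import link as _link
from .linking import score as _score
from .normalization import NormalizationConfig, filter_content_words, normalize, tokenize

__all__ = [
    "Annotation",
    "build_patterns",
    "match_more_words",
    "match_one_word",
    "match_two_word",
    "recognize",
    "recognize_all",
    "resolve_offsets",
    "wildcard_match",
]


@dataclass(frozen=True)
class Annotation:
    """A recognized mention in the original text.

    ``surface`` is exactly ``text[start:end]``; ``term`` is the normalized
    lexicon entry it matched; ``uri`` and ``entity_type`` are filled when a
    links table / lexicon name are available.
    """

    start: int
    end: int
    surface: str
    term: str
    uri: str | None = None
    entity_type: str | None = None
    score: float | None = None

    def span(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.term)


def build_patterns(
    content_words: Sequence[str],
) -> tuple[set[str], set[tuple[str, str]]]:
    """One-word and two-word alternation patterns from the content words.

    The two-word pattern holds all *consecutive* pairs of the filtered word
    sequence — pairs that may span removed stop-words; offset resolution
    later discards any term matched only through such a spurious pair.
    """
    words = set(content_words)
    pairs = set(zip(content_words, content_words[1:]))
    return words, pairs


def wildcard_match(candidate: str, entry: str) -> bool:
    """Index-time match of a text-side *candidate* against a lexicon *entry*.

    True iff both strings have equal length and, position by position, the
    characters are equal or the candidate character is ``.`` and the entry
    character is not a space.  Spaces must align exactly.
    """
    if len(candidate) != len(entry):
        return False
    for c, e in zip(candidate, entry):
        if c == e:
            continue
        if c == "." and e != " ":
            continue
        return False
    return True


def match_one_word(
    one_word_pattern: Iterable[str], lex: CompiledLexicon
) -> set[str]:
    """One-word lexicon entries matched in full by some pattern word."""
    pattern = list(one_word_pattern)
    return {
        entry
        for entry in lex.one_word
        if any(wildcard_match(word, entry) for word in pattern)
    }


def match_two_word(
    two_word_pattern: Iterable[tuple[str, str]], lex: CompiledLexicon
) -> set[str]:
    """Two-word lexicon entries matched by some consecutive word pair."""
    joined = [f"{a} {b}" for a, b in two_word_pattern]
    return {
        entry
        for entry in lex.two_word
        if any(wildcard_match(pair, entry) for pair in joined)
    }


def match_more_words(
    two_word_pattern: Iterable[tuple[str, str]], lex: CompiledLexicon
) -> list[str]:
    """Candidate 3+-word terms via the two-stage prefix lookup.

    Stage 1 matches the word pairs against the first-two-words part; stage 2
    returns every more-words term whose first two words equal a matched
    prefix.  The result is provisional: a candidate is only annotated if it
    actually occurs in the original text.
    """
    joined = [f"{a} {b}" for a, b in two_word_pattern]
    prefixes = {
        entry
        for entry in lex.first_two_words
        if any(wildcard_match(pair, entry) for pair in joined)
    }
    if not prefixes:
        return []
    return [
        term
        for term in lex.more_words
        if " ".join(term.split(" ")[:2]) in prefixes
    ]


@lru_cache(maxsize=4096)
def _term_pattern(term: str) -> re.Pattern[str]:
    """Compile the offset-resolution regex for a normalized term."""
    parts = []
    for ch in term:
        if ch == ".":
            parts.append(r"\S")  # any single non-whitespace character
        elif ch == " ":
            parts.append(r"[\s.]+")  # word gap: whitespace and/or full stops
        else:
            parts.append(re.escape(ch))
    return re.compile("".join(parts), re.IGNORECASE)


def resolve_offsets(
    terms: Iterable[str],
    original_text: str,
    config: NormalizationConfig | None = None,
) -> list[tuple[int, int, str, str]]:
    """Locate every occurrence of each term in the original text.

    Returns ``(start, end, surface, term)`` tuples with 0-based,
    end-exclusive character offsets.  Matching is case-insensitive, honors
    the wildcard and gap rules described in the module docstring, requires
    both match boundaries to not be adjacent to a letter or digit, and
    enforces the minimum entity length on the surface span.  Terms that never
    occur yield nothing.
    """
    config = config or NormalizationConfig()
    n = len(original_text)
    results: list[tuple[int, int, str, str]] = []
    for term in terms:
        pattern = _term_pattern(term)
        for start in range(n):
            if start > 0 and original_text[start - 1].isalnum():
                continue
            match = pattern.match(original_text, start)
            if match is None:
                continue
            end = match.end()
            if end < n and original_text[end].isalnum():
                continue
            if end - start < config.min_entity_length:
                continue
            results.append((start, end, original_text[start:end], term))
    return results


def recognize(
    text: str,
    lex: CompiledLexicon,
    links: LinksTable | None = None,
    config: NormalizationConfig | None = None,
    entity_type: str | None = None,
) -> list[Annotation]:
    """Full pipeline: normalize, filter, match, resolve, link, and score.

    Returns annotations sorted by ``(start, end, term)``.  Partial overlaps
    (a shorter term inside or beside a longer one) are kept; exact duplicates
    (same term, same span) are collapsed.  An empty text yields an empty
    list.
    """
    if not isinstance(lex, CompiledLexicon):
        raise TypeError(
            "recognize requires a CompiledLexicon; compile the lexicon first"
        )
    config = config or NormalizationConfig()
    if not text:
        return []

    content_words = filter_content_words(tokenize(normalize(text)), config)
    one_word_pattern, two_word_pattern = build_patterns(content_words)
    matched = sorted(
        match_one_word(one_word_pattern, lex)
        | match_two_word(two_word_pattern, lex)
    )
    candidates = match_more_words(two_word_pattern, lex)

    etype = entity_type if entity_type is not None else lex.name
    annotations: dict[tuple[int, int, str], Annotation] = {}
    for start, end, surface, term in resolve_offsets(
        matched + candidates, text, config
    ):
        key = (start, end, term)
        if key in annotations:
            continue
        annotations[key] = Annotation(
            start=start,
            end=end,
            surface=surface,
            term=term,
            uri=_link(term, links),
            entity_type=etype,
            score=_score(end - start),
        )
    return sorted(annotations.values(), key=Annotation.span)


def recognize_all(
    text: str,
    lexicons: Sequence[tuple[CompiledLexicon, LinksTable | None]],
    config: NormalizationConfig | None = None,
) -> list[Annotation]:
    """Annotate with several lexicons at once, tagging each entity type.

    Terms present in more than one lexicon are ambiguous across types and
    are reported once under the "Unknown" type (without a URI, since the
    competing lexicons may link the term differently).
    """
    term_sets = [
        set(lex.all_terms()) for lex, _ in lexicons
    ]
    counts: dict[str, int] = {}
    for terms in term_sets:
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    overlap = {t for t, c in counts.items() if c >= 2}

    merged: dict[tuple[int, int, str], Annotation] = {}
    for lex, links in lexicons:
        for ann in recognize(text, lex, links, config):
            if ann.term in overlap:
                ann = replace(ann, entity_type="Unknown", uri=None)
            merged.setdefault(ann.span(), ann)
    return sorted(merged.values(), key=Annotation.span)
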