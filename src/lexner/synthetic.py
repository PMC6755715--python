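"""Synthetic corpora with planted mentions, and a brute-force oracle.

The generator builds a random lexicon (terms of 1–5 words, each word at
least 3 letters and never a stop-word) and a carrier text of filler words
into which a chosen number of mentions is planted.  Planted surfaces are
*decorated* only with transformations the matching contract is specified to
survive — case changes, extra whitespace, full stops inside word gaps, and
substitution of one special character for another — never by touching an
alphanumeric character.  The exact character offsets of every planted
mention are recorded, so recall can be measured directly.

``naive_recognize`` is an independent oracle for equivalence testing: it
scans the whole text once per lexicon term with a recursive matcher, using
the same normalization and location *relations* as the production recognizer
but none of its index machinery (no four-part split, no pattern inversion).
Gap matching is resolved longest-gap-first with backtracking, which realizes
the same greedy semantics as the production regular expressions.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from pathlib import Path

from .lexicon import RawLexicon
from .normalization import (
    NormalizationConfig,
    default_stopwords,
    filter_content_words,
    normalize,
    tokenize,
)
from .recognizer import wildcard_match

__all__ = [
    "DECORATION_LEVELS",
    "SyntheticCorpus",
    "generate",
    "naive_recognize",
]

_SPECIALS = "-/+&;:"
_SEPARATORS = (" ", " ", " ", ". ", " . ", " , ", " ; ")
_GAPS = (" ", "  ", "   ", ". ", " . ")

DECORATION_LEVELS = ("none", "case", "whitespace", "special", "mixed")


@dataclass
class SyntheticCorpus:
    """A generated (lexicon, text, ground truth) triple."""

    seed: int
    lexicon: RawLexicon
    text: str
    truth: list[tuple[int, int, str]]  # (start, end, normalized term)

    def save(self, directory: str | Path) -> None:
        """Serialize as ``<name>.txt`` plus ``<name>_truth.tsv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        name = self.lexicon.name
        (directory / f"{name}.txt").write_text(self.text, "utf-8")
        self.lexicon.save(directory / f"{name}_lexicon.txt")
        rows = "".join(f"{s}\t{e}\t{t}\n" for s, e, t in self.truth)
        (directory / f"{name}_truth.tsv").write_text(rows, "utf-8")

    @classmethod
    def load(cls, name: str, directory: str | Path) -> "SyntheticCorpus":
        directory = Path(directory)
        text = (directory / f"{name}.txt").read_text("utf-8")
        lexicon = RawLexicon.from_file(
            directory / f"{name}_lexicon.txt", name=name
        )
        truth = []
        for line in (directory / f"{name}_truth.tsv").read_text(
            "utf-8"
        ).splitlines():
            start, end, term = line.split("\t")
            truth.append((int(start), int(end), term))
        return cls(seed=-1, lexicon=lexicon, text=text, truth=truth)


def _word(rng: random.Random, stop: frozenset[str]) -> str:
    while True:
        w = "".join(
            rng.choice(string.ascii_lowercase)
            for _ in range(rng.randint(3, 8))
        )
        if w not in stop:
            return w


def _term(rng: random.Random, stop: frozenset[str]) -> str:
    n_words = rng.choices((1, 2, 3, 4, 5), weights=(30, 30, 20, 12, 8))[0]
    words = []
    for _ in range(n_words):
        w = _word(rng, stop)
        if rng.random() < 0.25 and len(w) >= 5:
            # special character inside a word -> a '.' wildcard once compiled
            cut = rng.randint(2, len(w) - 2)
            w = w[:cut] + rng.choice(_SPECIALS) + w[cut:]
        words.append(w)
    term = " ".join(words)
    if rng.random() < 0.3:
        term = term.capitalize()
    return term


def _decorate(rng: random.Random, term: str, level: str) -> str:
    if level == "mixed":
        level = rng.choice(("none", "case", "whitespace", "special"))
    if level == "none":
        return term
    if level == "case":
        return "".join(
            ch.upper() if rng.random() < 0.5 else ch.lower() for ch in term
        )
    if level == "whitespace":
        return rng.choice(_GAPS).join(term.split(" "))
    if level == "special":
        return "".join(
            rng.choice(_SPECIALS) if ch in _SPECIALS else ch for ch in term
        )
    raise ValueError(f"unknown decoration level {level!r}")


def generate(
    seed: int,
    n_terms: int = 8,
    n_mentions: int = 10,
    decoration_level: str = "mixed",
) -> SyntheticCorpus:
    """Build a reproducible corpus with *n_mentions* planted ground truths.

    Mentions are always delimited by non-alphanumeric separators, and
    separators other than the full stop are never glued onto a mention (a
    glued comma would change the adjacent token and, by design, defeat the
    exact index match).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if decoration_level not in DECORATION_LEVELS:
        raise ValueError(f"unknown decoration level {decoration_level!r}")
    rng = random.Random(seed)
    stop = default_stopwords()

    raw_terms: list[str] = []
    seen: set[str] = set()
    while len(raw_terms) < n_terms:
        t = _term(rng, stop)
        if normalize(t) not in seen:
            seen.add(normalize(t))
            raw_terms.append(t)

    fillers = [_word(rng, frozenset()) for _ in range(12)] + [
        "the", "of", "and", "in", "was", "were", "is",
    ]

    parts: list[str] = []
    pos = 0
    truth: list[tuple[int, int, str]] = []

    def emit(chunk: str) -> None:
        nonlocal pos
        parts.append(chunk)
        pos += len(chunk)

    def emit_fillers(k: int) -> None:
        for _ in range(k):
            emit(rng.choice(fillers))
            emit(rng.choice(_SEPARATORS))

    emit_fillers(rng.randint(0, 3))
    for _ in range(n_mentions):
        term = rng.choice(raw_terms)
        surface = _decorate(rng, term, decoration_level)
        truth.append((pos, pos + len(surface), normalize(term)))
        emit(surface)
        emit(rng.choice(_SEPARATORS))
        emit_fillers(rng.randint(0, 4))
    emit(rng.choice(fillers))
    emit(".")

    return SyntheticCorpus(
        seed=seed,
        lexicon=RawLexicon(f"synthetic{seed}", raw_terms),
        text="".join(parts),
        truth=sorted(truth),
    )


def _match_from(term: str, k: int, text: str, j: int) -> int | None:
    """Greedy recursive matcher: end offset of a match of term[k:] at j."""
    if k == len(term):
        return j
    ch = term[k]
    if ch == " ":
        stop = j
        while stop < len(text) and (
            text[stop].isspace() or text[stop] == "."
        ):
            stop += 1
        for cut in range(stop, j, -1):  # longest gap first
            end = _match_from(term, k + 1, text, cut)
            if end is not None:
                return end
        return None
    if ch == ".":
        if j < len(text) and not text[j].isspace():
            return _match_from(term, k + 1, text, j + 1)
        return None
    if j < len(text) and text[j].lower() == ch:
        return _match_from(term, k + 1, text, j + 1)
    return None


def _locate_all(
    term: str, text: str, min_length: int
) -> list[tuple[int, int]]:
    n = len(text)
    spans = []
    for start in range(n):
        if start > 0 and text[start - 1].isalnum():
            continue
        end = _match_from(term, 0, text, start)
        if end is None:
            continue
        if end < n and text[end].isalnum():
            continue
        if end - start < min_length:
            continue
        spans.append((start, end))
    return spans


def naive_recognize(
    text: str,
    raw: RawLexicon,
    config: NormalizationConfig | None = None,
) -> list[tuple[int, int, str]]:
    """Brute-force recognition: exhaustive per-term scanning, no index.

    For each distinct normalized term, decide whether the text mentions it —
    a content word must match a one-word term, a consecutive content-word
    pair must match a two-word term or the first two words of a longer term —
    and if so report every located occurrence in the original text.
    """
    config = config or NormalizationConfig()
    content = filter_content_words(tokenize(normalize(text)), config)
    word_set = set(content)
    pair_set = {f"{a} {b}" for a, b in zip(content, content[1:])}

    results: set[tuple[int, int, str]] = set()
    seen: set[str] = set()
    for raw_term in raw.terms:
        term = normalize(raw_term)
        if term in seen or not any(c.isalnum() for c in term):
            continue
        seen.add(term)
        words = term.split(" ")
        if len(words) == 1:
            mentioned = any(wildcard_match(w, term) for w in word_set)
        elif len(words) == 2:
            mentioned = any(wildcard_match(p, term) for p in pair_set)
        else:
            prefix = " ".join(words[:2])
            mentioned = any(wildcard_match(p, prefix) for p in pair_set)
        if not mentioned:
            continue
        for start, end in _locate_all(term, text, config.min_entity_length):
            results.add((start, end, term))
    return sorted(results)
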