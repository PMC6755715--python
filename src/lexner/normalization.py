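"""Text rewriting shared by the offline lexicon compiler and the online recognizer.

Lexicon terms and input text are rewritten with the same five rules, in this
order, so that subsequent matching can be exact on the rewritten strings:

1. lowercase everything;
2. remove full stops and other *special* characters — anything that is
   neither alphanumeric nor whitespace — at the edges of a word (so the
   abbreviation dot of "E. coli" and a trailing comma vanish);
3. replace every special character left *inside* a word, e.g. the hyphen of
   "acid-adenine", with a full stop, which later acts as a single-character
   wildcard;
4. collapse each run of whitespace to a single space;
5. strip leading and trailing spaces.

"Alphanumeric" means Unicode letter or digit, so multi-byte characters such as
``α`` are letters, not specials, and survive untouched.  The result therefore
contains only lowercase alphanumerics, single spaces, and ``.`` wildcards, and
the rewrite is idempotent.

The online side additionally drops *non-content* words — stop-words and words
shorter than a minimum entity length (default 3 characters, below which most
matches are spurious two-letter acronym hits) — before building search
patterns.  Those two knobs live in :class:`NormalizationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "NormalizationConfig",
    "default_stopwords",
    "filter_content_words",
    "load_stopwords",
    "normalize",
    "tokenize",
]

def normalize(text: str) -> str:
    """Apply the five rewrite rules to *text*.

    Total and idempotent; the empty string maps to itself.

    >>> normalize("nicotinic acid-adenine dinucleotide phosphate")
    'nicotinic acid.adenine dinucleotide phosphate'
    >>> normalize("  E. coli  ")
    'e coli'
    """
    lowered = "".join(" " if ch.isspace() else ch for ch in text.lower())
    out_tokens = []
    for token in lowered.split(" "):
        alnum_at = [i for i, ch in enumerate(token) if ch.isalnum()]
        if not alnum_at:
            continue  # token of bare punctuation: removed entirely
        core = token[alnum_at[0] : alnum_at[-1] + 1]
        out_tokens.append(
            "".join(ch if ch.isalnum() else "." for ch in core)
        )
    return " ".join(out_tokens)


def tokenize(normalized: str) -> list[str]:
    """Split an already-normalized string into its words.

    A word is a maximal run of non-space characters; joining the result with
    single spaces reproduces the input.
    """
    if not normalized:
        return []
    return normalized.split(" ")


def _read_wordlist(text: str) -> frozenset[str]:
    words = (line.strip() for line in text.splitlines())
    return frozenset(w for w in words if w and not w.startswith("#"))


@lru_cache(maxsize=None)
def default_stopwords() -> frozenset[str]:
    """The packaged English stop-word list (one word per line, UTF-8)."""
    data = resources.files("lexner").joinpath("data/stopwords.txt").read_text("utf-8")
    return _read_wordlist(data)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a user-supplied stop-word file: plain text, one word per line."""
    return _read_wordlist(Path(path).read_text("utf-8"))


@dataclass(frozen=True)
class NormalizationConfig:
    """Tunable parameters of the online text processing.

    Parameters
    ----------
    min_entity_length:
        Minimum number of characters (≥ 1) a word must have to take part in
        matching, and a recognized span must have to be reported.  Default 3.
    stopwords:
        Words removed from the input text before pattern construction.  When
        ``None``, the packaged default list is used.  The words are stored in
        normalized (lowercase) form.
    """

    min_entity_length: int = 3
    stopwords: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.min_entity_length < 1:
            raise ValueError("min_entity_length must be >= 1")
        if self.stopwords is None:
            sw = default_stopwords()
        else:
            sw = frozenset(normalize(w) for w in self.stopwords) - {""}
        object.__setattr__(self, "stopwords", sw)


def filter_content_words(
    words: Iterable[str], config: NormalizationConfig
) -> list[str]:
    """Drop stop-words and words shorter than the minimum entity length.

    Order is preserved; the result is a subsequence of the input.
    """
    stop = config.stopwords
    min_len = config.min_entity_length
    return [w for w in words if w not in stop and len(w) >= min_len]
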