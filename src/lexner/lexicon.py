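"""Offline lexicon compilation: the four-part word-count index and links table.

A lexicon is a flat list of terms, one per line.  To support inverted
recognition — where the words of the *input text* are the patterns matched
against the lexicon rather than the other way round — the compiler normalizes
every term, removes duplicates, and partitions the vocabulary by word count
into four parts:

``one_word``
    terms made of a single word;
``two_word``
    terms made of exactly two words;
``more_words``
    terms of three or more words, kept as an ordered (sorted) list;
``first_two_words``
    the two-word prefixes of the ``more_words`` entries, enabling a two-stage
    lookup: a consecutive word pair from the text first selects matching
    prefixes, and only terms behind a selected prefix become candidates.

Entity linking uses a separate two-column (term TAB URI) table, sorted by
line, where the first entry for a term wins.  Both the lexicon and the links
table can alternatively be harvested from an OWL/RDF-XML ontology: every
``rdfs:label``, ``oboInOwl:hasExactSynonym`` and ``oboInOwl:hasRelatedSynonym``
of each URI-bearing ``owl:Class`` becomes a term linked to the class URI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdflib import Graph, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .normalization import normalize

__all__ = [
    "CompiledLexicon",
    "InvalidLexiconError",
    "LinksTable",
    "RawLexicon",
    "UncompiledLexiconError",
    "build_overlap_lexicon",
    "compile_lexicon",
    "list_compiled",
    "load_compiled",
    "parse_owl",
    "save_compiled",
]

logger = logging.getLogger(__name__)

OBO_IN_OWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")

#: Annotation properties harvested from an ontology, in harvest order.
SYNONYM_PREDICATES = (
    RDFS.label,
    OBO_IN_OWL.hasExactSynonym,
    OBO_IN_OWL.hasRelatedSynonym,
)


class InvalidLexiconError(ValueError):
    """Raised when a lexicon has no usable terms after cleanup."""


class UncompiledLexiconError(FileNotFoundError):
    """Raised when a compiled lexicon is loaded but an index file is missing."""


def _has_content(term: str) -> bool:
    return any(ch.isalnum() for ch in term)


@dataclass
class RawLexicon:
    """A named list of raw (un-normalized) terms, one per source line."""

    name: str
    terms: list[str]

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "RawLexicon":
        path = Path(path)
        lines = path.read_text("utf-8").splitlines()
        terms = [line.strip() for line in lines if line.strip()]
        return cls(name or path.stem, terms)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("".join(t + "\n" for t in self.terms), "utf-8")


@dataclass
class CompiledLexicon:
    """The four-part index over normalized terms (see module docstring)."""

    name: str
    one_word: set[str]
    two_word: set[str]
    more_words: list[str]
    first_two_words: set[str]

    @property
    def n_terms(self) -> int:
        return len(self.one_word) + len(self.two_word) + len(self.more_words)

    def all_terms(self) -> Iterator[str]:
        yield from sorted(self.one_word)
        yield from sorted(self.two_word)
        yield from self.more_words


def compile_lexicon(raw: RawLexicon) -> CompiledLexicon:
    """Normalize, deduplicate, and partition a raw lexicon by word count.

    Terms that normalize to the empty string or to bare wildcards (no
    alphanumeric character left) are dropped with a warning.

    Raises
    ------
    InvalidLexiconError
        If no usable term remains after cleanup.
    """
    seen: set[str] = set()
    kept: list[str] = []
    for term in raw.terms:
        norm = normalize(term)
        if not _has_content(norm):
            if term.strip():
                logger.warning(
                    "lexicon %r: dropping term %r (nothing left after "
                    "normalization)", raw.name, term,
                )
            continue
        if norm not in seen:
            seen.add(norm)
            kept.append(norm)
    if not kept:
        raise InvalidLexiconError(
            f"empty lexicon: {raw.name!r} has no usable terms after cleanup"
        )

    one_word: set[str] = set()
    two_word: set[str] = set()
    more_words: list[str] = []
    for term in kept:
        spaces = term.count(" ")
        if spaces == 0:
            one_word.add(term)
        elif spaces == 1:
            two_word.add(term)
        else:
            more_words.append(term)
    more_words.sort()
    first_two = {" ".join(t.split(" ")[:2]) for t in more_words}
    return CompiledLexicon(raw.name, one_word, two_word, more_words, first_two)


class LinksTable:
    """Ordered mapping from normalized term to URI; first entry wins.

    Entries are sorted lexicographically by (term, uri), mirroring a plain
    line sort of a two-column ``term<TAB>uri`` file, and lookup returns the
    URI of the first entry whose term equals the query.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        entries: list[tuple[str, str]] = []
        for term, uri in pairs:
            norm = normalize(term)
            if not _has_content(norm):
                logger.warning("links table: dropping unusable term %r", term)
                continue
            entries.append((norm, str(uri).strip()))
        entries.sort()
        self.entries: list[tuple[str, str]] = entries
        self._first: dict[str, str] = {}
        for term, uri in entries:
            self._first.setdefault(term, uri)

    def lookup(self, term: str) -> str | None:
        """URI of the first entry matching *term* exactly, or ``None``."""
        return self._first.get(normalize(term))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinksTable):
            return NotImplemented
        return self.entries == other.entries

    def __repr__(self) -> str:  # pragma: no cover
        return f"LinksTable({len(self.entries)} entries)"

    @classmethod
    def from_file(cls, path: str | Path) -> "LinksTable":
        pairs = []
        for lineno, line in enumerate(
            Path(path).read_text("utf-8").splitlines(), 1
        ):
            if not line.strip():
                continue
            if "\t" not in line:
                logger.warning("%s:%d: no tab separator, skipped", path, lineno)
                continue
            term, uri = line.split("\t", 1)
            pairs.append((term, uri))
        return cls(pairs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{t}\t{u}\n" for t, u in self.entries), "utf-8"
        )


def parse_owl(
    source: str | Path, name: str = "ontology"
) -> tuple[RawLexicon, LinksTable]:
    """Harvest a lexicon and links table from an OWL/RDF-XML document.

    *source* may be a path to an ``.owl`` file or the XML content itself.
    Labels and exact/related synonyms of every ``owl:Class`` that carries its
    own URI are collected; anonymous classes are skipped with a warning.
    Malformed XML propagates the parser's error.
    """
    graph = Graph()
    text = str(source)
    if isinstance(source, Path) or not text.lstrip().startswith("<"):
        graph.parse(str(source), format="xml")
    else:
        graph.parse(data=text, format="xml")

    terms: list[str] = []
    pairs: list[tuple[str, str]] = []
    for cls in set(graph.subjects(RDF.type, OWL.Class)):
        if not isinstance(cls, URIRef):
            logger.warning("skipping owl:Class without its own URI: %r", cls)
            continue
        for predicate in SYNONYM_PREDICATES:
            for value in graph.objects(cls, predicate):
                term = str(value).strip()
                if term:
                    terms.append(term)
                    pairs.append((term, str(cls)))
    terms.sort()
    return RawLexicon(name, terms), LinksTable(pairs)


# On-disk layout of a compiled lexicon: (human-readable part name, suffix).
_PARTS = (
    ("one-word", "_word1.txt"),
    ("two-word", "_word2.txt"),
    ("more-words", "_words.txt"),
    ("first-two-words", "_words2.txt"),
)


def save_compiled(
    lex: CompiledLexicon,
    links: LinksTable | None = None,
    directory: str | Path = ".",
) -> list[Path]:
    """Write the four index files (plus the links TSV when given).

    Files are plain UTF-8 text, one term per line:
    ``<name>_word1.txt``, ``<name>_word2.txt``, ``<name>_words.txt``,
    ``<name>_words2.txt`` and optionally ``<name>_links.tsv``.
    :func:`load_compiled` is the exact inverse.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    contents = (
        sorted(lex.one_word),
        sorted(lex.two_word),
        list(lex.more_words),
        sorted(lex.first_two_words),
    )
    written: list[Path] = []
    for (_, suffix), lines in zip(_PARTS, contents):
        path = directory / f"{lex.name}{suffix}"
        try:
            path.write_text("".join(t + "\n" for t in lines), "utf-8")
        except OSError as exc:  # re-raise with path context
            raise OSError(f"cannot write lexicon part {path}: {exc}") from exc
        written.append(path)
    if links is not None:
        path = directory / f"{lex.name}_links.tsv"
        links.save(path)
        written.append(path)
    return written


def load_compiled(
    name: str, directory: str | Path = "."
) -> tuple[CompiledLexicon, LinksTable | None]:
    """Load a compiled lexicon saved by :func:`save_compiled`."""
    directory = Path(directory)
    parts: list[list[str]] = []
    for part, suffix in _PARTS:
        path = directory / f"{name}{suffix}"
        if not path.exists():
            raise UncompiledLexiconError(
                f"lexicon {name!r} is not compiled: missing {part} file {path}"
            )
        parts.append(
            [line for line in path.read_text("utf-8").splitlines() if line]
        )
    lex = CompiledLexicon(
        name, set(parts[0]), set(parts[1]), parts[2], set(parts[3])
    )
    links_path = directory / f"{name}_links.tsv"
    links = LinksTable.from_file(links_path) if links_path.exists() else None
    return lex, links


def list_compiled(directory: str | Path) -> list[str]:
    """Names of all fully compiled lexicons found in *directory*."""
    directory = Path(directory)
    if not directory.is_dir():
        return []
    names = sorted(
        p.name[: -len("_word1.txt")]
        for p in directory.glob("*_word1.txt")
    )
    return [
        n
        for n in names
        if all((directory / f"{n}{suffix}").exists() for _, suffix in _PARTS)
    ]


def build_overlap_lexicon(
    lexicons: list[CompiledLexicon], name: str = "Unknown"
) -> RawLexicon:
    """Terms present in at least two of the given lexicons.

    Such terms are ambiguous across entity types and are conventionally
    reported under a catch-all "Unknown" type.
    """
    if len(lexicons) < 2:
        raise ValueError("overlap requires at least two lexicons")
    counts: dict[str, int] = {}
    for lex in lexicons:
        for term in set(lex.all_terms()):
            counts[term] = counts.get(term, 0) + 1
    return RawLexicon(name, sorted(t for t, c in counts.items() if c >= 2))
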