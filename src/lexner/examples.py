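"""Worked example: a four-compound chemical lexicon and a sentence using it.

The lexicon lists four ChEBI compounds; the sentence mentions two of them
(one a prefix of the other, exercising partial overlap) plus α-maltose.  The
links table maps each term to its ChEBI class URI.  Annotating the sentence
with defaults yields "nicotinic acid" at character offsets 14 and 65 and
"nicotinic acid D-ribonucleotide" at 14–45.
"""

from __future__ import annotations

from .lexicon import CompiledLexicon, LinksTable, RawLexicon, compile_lexicon

__all__ = [
    "LEXICON_NAME",
    "LEXICON_TERMS",
    "LINKS",
    "SENTENCE",
    "compiled",
    "links_table",
    "raw_lexicon",
]

LEXICON_NAME = "compounds"

LEXICON_TERMS = (
    "α-maltose",
    "nicotinic acid",
    "nicotinic acid D-ribonucleotide",
    "nicotinic acid-adenine dinucleotide phosphate",
)

_OBO = "http://purl.obolibrary.org/obo/"

LINKS = (
    ("α-maltose", _OBO + "CHEBI_18167"),
    ("nicotinic acid", _OBO + "CHEBI_15940"),
    ("nicotinic acid D-ribonucleotide", _OBO + "CHEBI_15763"),
    ("nicotinic acid-adenine dinucleotide phosphate", _OBO + "CHEBI_76072"),
)

SENTENCE = (
    "α-maltose and nicotinic acid D-ribonucleotide "
    "were found but not nicotinic acid"
)


def raw_lexicon() -> RawLexicon:
    return RawLexicon(LEXICON_NAME, list(LEXICON_TERMS))


def compiled() -> CompiledLexicon:
    return compile_lexicon(raw_lexicon())


def links_table() -> LinksTable:
    return LinksTable(LINKS)
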