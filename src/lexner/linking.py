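"""Entity linking, confidence scoring, and TSV serialization.

Linking is a first-exact-match lookup of the recognized (normalized) term in
the sorted links table.  The confidence score of a mention is::

    score = 1 - 1 / ln(nc)

where ``nc`` is the number of characters of the recognized span (``end -
start``, counting internal spaces).  Longer mentions are assumed to be less
ambiguous and thus more trustworthy; with the default minimum entity length
of 3 the score ranges over [0.08976, 1).

Two output dialects are provided:

* plain TSV — ``start  end  surface  [uri]`` (Fig-9/10 style);
* BeCalm TSV — ``document_id  section  start  end  score  surface
  entity_type  uri`` with the score printed at 5 decimals and an empty last
  column when no link is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, TextIO

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import LinksTable
    from .recognizer import Annotation

__all__ = [
    "ScoredOutputRow",
    "format_score",
    "link",
    "score",
    "write_becalm_tsv",
    "write_tsv",
]


def link(term: str, links: "LinksTable | None") -> str | None:
    """URI of the first exact match of *term* in the links table, if any."""
    if links is None:
        return None
    return links.lookup(term)


def score(nc: int) -> float:
    """Confidence ``1 - 1/ln(nc)`` for a span of *nc* characters.

    Strictly increasing in ``nc`` and always below 1.  ``nc`` must be at
    least 2 (``ln(1) = 0``); recognized spans are always >= the minimum
    entity length, 3 by default, for which the score is 0.08976.
    """
    if nc < 2:
        raise ValueError(f"score undefined for nc={nc} (need nc >= 2)")
    return 1.0 - 1.0 / math.log(nc)


def format_score(value: float) -> str:
    """Render a score at the fixed 5-decimal output precision (half-even)."""
    return f"{value:.5f}"


@dataclass(frozen=True)
class ScoredOutputRow:
    """One BeCalm TSV row; column order is the field order below."""

    document_id: str
    section: str
    start: int
    end: int
    score: float
    surface: str
    entity_type: str
    uri: str | None = None

    @classmethod
    def from_annotation(
        cls, document_id: str, section: str, ann: "Annotation"
    ) -> "ScoredOutputRow":
        return cls(
            document_id=document_id,
            section=section,
            start=ann.start,
            end=ann.end,
            score=ann.score if ann.score is not None else score(ann.end - ann.start),
            surface=ann.surface,
            entity_type=ann.entity_type or "",
            uri=ann.uri,
        )

    def fields(self) -> tuple[str, ...]:
        return (
            self.document_id,
            self.section,
            str(self.start),
            str(self.end),
            format_score(self.score),
            self.surface,
            self.entity_type,
            self.uri or "",
        )


def write_tsv(annotations: Iterable["Annotation"], sink: TextIO) -> None:
    """Write plain TSV rows: start, end, surface, and URI when linked."""
    for ann in annotations:
        cols = [str(ann.start), str(ann.end), ann.surface]
        if ann.uri is not None:
            cols.append(ann.uri)
        sink.write("\t".join(cols) + "\n")


def write_becalm_tsv(
    document_id: str,
    section: str,
    annotations: Iterable["Annotation"],
    sink: TextIO,
) -> None:
    """Write BeCalm TSV rows (see module docstring for the column order)."""
    if not document_id or not section:
        raise ValueError("BeCalm TSV output requires a document id and section")
    for ann in annotations:
        row = ScoredOutputRow.from_annotation(document_id, section, ann)
        sink.write("\t".join(row.fields()) + "\n")
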