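#!/usr/bin/env python
"""Evaluate the recognizer on a locally supplied gold-standard corpus.

Reports micro-averaged precision, recall and F1 for span recognition (NER:
exact start/end offsets) and for recognition plus linking (NER+NEL: offsets
and URI).  No target value is asserted; this is a reporting tool for users
who have a corpus such as the HPO gold standard available locally.

Corpus layout: a directory of ``<id>.txt`` documents with, for each, a
``<id>.ann`` gold file of tab-separated ``start  end  surface  [uri]`` rows
(0-based, end-exclusive character offsets).

Usage:
    python scripts/evaluate_corpus.py --corpus DIR \
        (--ontology hp.owl | --lexicon terms.txt [--links links.tsv])
"""

from __future__ import annotations

import argparse
from pathlib import Path

from lexner import (
    EntityRecognizer,
    LinksTable,
    RawLexicon,
    parse_owl,
)


def read_gold(path: Path) -> tuple[set[tuple[int, int]], set[tuple[int, int, str]]]:
    spans: set[tuple[int, int]] = set()
    linked: set[tuple[int, int, str]] = set()
    for line in path.read_text("utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        start, end = int(parts[0]), int(parts[1])
        spans.add((start, end))
        if len(parts) > 3 and parts[3]:
            linked.add((start, end, parts[3]))
    return spans, linked


def prf(tp: int, n_pred: int, n_gold: int) -> tuple[float, float, float]:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--corpus", type=Path, required=True)
    parser.add_argument("--ontology", type=Path)
    parser.add_argument("--lexicon", type=Path)
    parser.add_argument("--links", type=Path)
    args = parser.parse_args()

    if args.ontology:
        raw, links = parse_owl(args.ontology, name=args.ontology.stem)
    elif args.lexicon:
        raw = RawLexicon.from_file(args.lexicon)
        links = LinksTable.from_file(args.links) if args.links else None
    else:
        parser.error("provide --ontology or --lexicon")

    est = EntityRecognizer(name=raw.name).fit(raw, links=links)

    ner_tp = ner_pred = ner_gold = 0
    nel_tp = nel_pred = nel_gold = 0
    n_docs = 0
    for text_path in sorted(args.corpus.glob("*.txt")):
        gold_path = text_path.with_suffix(".ann")
        if not gold_path.exists():
            continue
        n_docs += 1
        gold_spans, gold_linked = read_gold(gold_path)
        annotations = est.annotate(text_path.read_text("utf-8"))
        pred_spans = {(a.start, a.end) for a in annotations}
        pred_linked = {
            (a.start, a.end, a.uri) for a in annotations if a.uri is not None
        }
        ner_tp += len(pred_spans & gold_spans)
        ner_pred += len(pred_spans)
        ner_gold += len(gold_spans)
        nel_tp += len(pred_linked & gold_linked)
        nel_pred += len(pred_linked)
        nel_gold += len(gold_linked)

    print(f"documents evaluated: {n_docs}")
    header = f"{'':8s}{'P':>8s}{'R':>8s}{'F':>8s}"
    print(header)
    for label, stats in (
        ("NER", prf(ner_tp, ner_pred, ner_gold)),
        ("NER+NEL", prf(nel_tp, nel_pred, nel_gold)),
    ):
        p, r, f = stats
        print(f"{label:8s}{p:8.4f}{r:8.4f}{f:8.4f}")


if __name__ == "__main__":
    main()
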