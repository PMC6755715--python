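# lexner

Minimal dictionary-lookup named-entity recognition (NER) and linking (NEL)
for the life sciences. Given nothing but a flat lexicon — one term per line,
e.g. ChEBI compound names, HPO phenotypes, or disease names — `lexner` finds
every mention of those terms in free text, reports exact character offsets,
optionally links each mention to its ontology URI, and scores it. No
training corpus, no model: if a vocabulary exists, the annotator exists.

## Method

**Offline.** Each term is normalized (lowercased; punctuation at word edges
dropped; special characters *inside* words — hyphens, slashes — replaced by
a `.` wildcard; whitespace collapsed) and the vocabulary is partitioned by
word count into four parts: *one-word* terms, *two-word* terms, *more-words*
terms (3+), and the *first-two-words* prefixes of the latter. An optional
two-column `term<TAB>URI` table, sorted with first-entry-wins lookup,
supports linking; both files can also be harvested automatically from an
OWL ontology (`rdfs:label`, `oboInOwl:hasExactSynonym`,
`oboInOwl:hasRelatedSynonym` of every URI-bearing `owl:Class`).

**Online — inverted recognition.** Instead of scanning the text once per
lexicon term (cost grows with lexicon size), the *words of the input text*
become the patterns. The text is normalized the same way, stop-words and
words under 3 characters are removed, and two alternation patterns are
built: all content words, and all consecutive content-word pairs. Three
jobs match them against the index: words against one-word terms, pairs
against two-word terms, and pairs against the first-two-words prefixes to
nominate 3+-word candidates. Every matched term is then located in the
*original* text — case-insensitively, with `.` matching any non-whitespace
character and word gaps absorbing whitespace/full stops, at non-alphanumeric
boundaries — which yields exact Unicode character offsets and discards
candidates the processed text only suggested. Partial overlaps are kept;
exact duplicates are not.

Each mention of `nc` characters gets the confidence score

    score = 1 − 1 / ln(nc)

(longer mentions are less ambiguous); with the minimum entity length of 3
the score ranges over [0.08976, 1).

## Worked example

`compounds.txt` lists four ChEBI compounds:

```
α-maltose
nicotinic acid
nicotinic acid D-ribonucleotide
nicotinic acid-adenine dinucleotide phosphate
```

```console
$ lexner compile compounds.txt --links compounds_links.tsv
compiled 'compounds': 1 one-word, 1 two-word, 2 more-words terms (2 two-word prefixes, 4 links)

$ lexner annotate compounds 'α-maltose and nicotinic acid D-ribonucleotide were found but not nicotinic acid'
0	9	α-maltose	http://purl.obolibrary.org/obo/CHEBI_18167
14	28	nicotinic acid	http://purl.obolibrary.org/obo/CHEBI_15940
14	45	nicotinic acid D-ribonucleotide	http://purl.obolibrary.org/obo/CHEBI_15763
65	79	nicotinic acid	http://purl.obolibrary.org/obo/CHEBI_15940
```

Columns are start offset, end offset (0-based characters, end-exclusive),
surface text, and linked URI. "nicotinic acid" is found twice, at 14 and
65; the first occurrence sits inside the longer match "nicotinic acid
D-ribonucleotide" (14–45) — a partial overlap the method deliberately
keeps. Note the index stores `nicotinic acid d.ribonucleotide`: the hyphen
became a wildcard, so the original hyphenated surface still matches.

With `--format becalm-tsv --doc-id 1 --section A` the rows gain document
id, section, score, and entity type:

```
1	A	14	28	0.62108	nicotinic acid	compounds	http://purl.obolibrary.org/obo/CHEBI_15940
```

(0.62108 = 1 − 1/ln 14 for the 14-character mention.)

The same pipeline is available as a scikit-learn-style estimator:

```python
from lexner import EntityRecognizer

est = EntityRecognizer(name="compounds").fit(
    ["ATP", "nicotinic acid"],
    links=[("nicotinic acid", "http://purl.obolibrary.org/obo/CHEBI_15940")],
)
for ann in est.annotate("ATP binds nicotinic acid"):
    print(ann.start, ann.end, ann.term, ann.uri)
# 0 3 atp None
# 10 24 nicotinic acid http://purl.obolibrary.org/obo/CHEBI_15940
```

`lexner annotate --all-lexicons` annotates with every compiled lexicon at
once, adding the lexicon name as the entity type; terms occurring in more
than one lexicon are reported under the type `Unknown`.

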