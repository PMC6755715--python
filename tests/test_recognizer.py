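"""Inverted recognition: patterns, matching jobs, offset resolution."""

import pytest

from lexner import (
    NormalizationConfig,
    RawLexicon,
    build_patterns,
    compile_lexicon,
    examples,
    match_more_words,
    match_one_word,
    match_two_word,
    recognize,
    recognize_all,
    resolve_offsets,
    wildcard_match,
)


def test_build_patterns_words_and_consecutive_pairs():
    ones, twos = build_patterns(["nicotinic", "acid", "found"])
    assert ones == {"nicotinic", "acid", "found"}
    assert twos == {("nicotinic", "acid"), ("acid", "found")}


def test_build_patterns_degenerate_inputs():
    assert build_patterns([]) == (set(), set())
    assert build_patterns(["atp"]) == ({"atp"}, set())


@pytest.mark.parametrize(
    ("candidate", "entry", "expected"),
    [
        ("acid.adenine", "acid.adenine", True),
        ("acid", "acid", True),
        ("acid3adenine", "acid.adenine", False),  # entry '.' needs a '.' pattern
        ("a.p", "atp", True),  # text-side '.' matches anything
        ("a.p", "app", True),
        ("atp", "a.p", False),
        ("nicotinic acid", "nicotinic acid", True),
        ("nicotinic.acid", "nicotinic acid", False),  # spaces must align
        ("acid", "acids", False),  # whole-entry match only
    ],
)
def test_wildcard_match(candidate, entry, expected):
    assert wildcard_match(candidate, entry) is expected


class TestMatchingJobs:
    def test_one_word_job(self, example_lexicon):
        assert match_one_word({"α.maltose", "was"}, example_lexicon) == {"α.maltose"}
        assert match_one_word(set(), example_lexicon) == set()

    def test_one_word_wildcard_matches_several_entries(self):
        lex = compile_lexicon(RawLexicon("x", ["atp", "app"]))
        assert match_one_word({"a.p"}, lex) == {"atp", "app"}

    def test_two_word_job(self, example_lexicon):
        assert match_two_word({("nicotinic", "acid")}, example_lexicon) == {
            "nicotinic acid"
        }
        assert match_two_word({("acid", "found")}, example_lexicon) == set()

    def test_more_words_prefix_selects_candidates(self, example_lexicon):
        # ("nicotinic", "acid") matches the prefix "nicotinic acid" but not
        # "nicotinic acid.adenine", so only the D-ribonucleotide term remains.
        assert match_more_words({("nicotinic", "acid")}, example_lexicon) == [
            "nicotinic acid d.ribonucleotide"
        ]
        assert match_more_words(set(), example_lexicon) == []

    def test_wildcard_pair_reaches_wildcard_prefix(self, example_lexicon):
        got = match_more_words({("nicotinic", "acid.adenine")}, example_lexicon)
        assert got == ["nicotinic acid.adenine dinucleotide phosphate"]


class TestResolveOffsets:
    def test_worked_sentence_occurrences(self):
        spans = resolve_offsets(["nicotinic acid"], examples.SENTENCE)
        assert [(s, e) for s, e, _, _ in spans] == [(14, 28), (65, 79)]
        assert all(
            examples.SENTENCE[s:e] == surface for s, e, surface, _ in spans
        )

    def test_gap_matches_abbreviation_full_stop(self):
        spans = resolve_offsets(["e coli"], "Found E. coli today")
        assert spans == [(6, 13, "E. coli", "e coli")]

    def test_word_boundaries_exclude_substring_hits(self):
        spans = resolve_offsets(["acid"], "acidic acid")
        assert spans == [(7, 11, "acid", "acid")]

    def test_term_wildcard_matches_any_nonspace_character(self):
        spans = resolve_offsets(["a.p"], "an a-p unit")
        assert spans == [(3, 6, "a-p", "a.p")]

    def test_absent_term_yields_nothing(self):
        assert resolve_offsets(["caffeine"], examples.SENTENCE) == []

    def test_minimum_length_applies_to_surface_span(self):
        config = NormalizationConfig(min_entity_length=20)
        assert resolve_offsets(["nicotinic acid"], examples.SENTENCE, config) == []

    def test_offsets_count_characters_not_bytes(self):
        # α is multi-byte in UTF-8; offsets must be character-based.
        spans = resolve_offsets(["α.maltose"], examples.SENTENCE)
        assert spans == [(0, 9, "α-maltose", "α.maltose")]


class TestRecognize:
    def test_worked_example_spans(self, example_lexicon):
        anns = recognize(examples.SENTENCE, example_lexicon)
        assert [a.span() for a in anns] == [
            (0, 9, "α.maltose"),
            (14, 28, "nicotinic acid"),
            (14, 45, "nicotinic acid d.ribonucleotide"),
            (65, 79, "nicotinic acid"),
        ]

    def test_partial_overlap_kept_duplicates_collapsed(self, example_lexicon):
        anns = recognize(examples.SENTENCE, example_lexicon)
        spans = [a.span() for a in anns]
        assert len(spans) == len(set(spans))
        # the short term nests inside the longer one at the same start
        assert (14, 28, "nicotinic acid") in spans
        assert (14, 45, "nicotinic acid d.ribonucleotide") in spans

    def test_annotation_invariants(self, example_lexicon, config):
        text = examples.SENTENCE
        for ann in recognize(text, example_lexicon):
            assert 0 <= ann.start < ann.end <= len(text)
            assert ann.surface == text[ann.start : ann.end]
            assert ann.end - ann.start >= config.min_entity_length
            assert ann.entity_type == "compounds"
            assert 0 < ann.score < 1

    def test_links_fill_the_uri(self, example_lexicon, example_links):
        anns = recognize(examples.SENTENCE, example_lexicon, example_links)
        uris = {a.term: a.uri for a in anns}
        assert uris["nicotinic acid"].endswith("CHEBI_15940")
        assert uris["α.maltose"].endswith("CHEBI_18167")

    def test_empty_text(self, example_lexicon):
        assert recognize("", example_lexicon) == []

    def test_stop_word_only_text(self, example_lexicon):
        assert recognize("was", example_lexicon) == []

    def test_uncompiled_lexicon_rejected(self):
        with pytest.raises(TypeError):
            recognize("text", RawLexicon("x", ["atp"]))

    def test_deterministic(self, example_lexicon, example_links):
        first = recognize(examples.SENTENCE, example_lexicon, example_links)
        second = recognize(examples.SENTENCE, example_lexicon, example_links)
        assert first == second

    def test_monotone_under_lexicon_growth(self):
        text = "α-maltose and nicotinic acid were found"
        small = compile_lexicon(RawLexicon("x", ["nicotinic acid"]))
        large = compile_lexicon(
            RawLexicon("x", ["nicotinic acid", "α-maltose", "found"])
        )
        small_spans = {a.span() for a in recognize(text, small)}
        large_spans = {a.span() for a in recognize(text, large)}
        assert small_spans <= large_spans

    def test_spurious_wildcard_match_is_filtered_by_resolution(self):
        # "a-p" normalizes to the pattern "a.p", which matches the entry
        # "atp" in the index, but "atp" never occurs in the original text.
        lex = compile_lexicon(RawLexicon("x", ["atp"]))
        assert recognize("an a-p unit", lex) == []

    def test_pair_spanning_a_stop_word_is_filtered(self):
        # "acid" and "found" become adjacent once "was" is removed, matching
        # a two-word entry in the index that the original text never shows.
        lex = compile_lexicon(RawLexicon("x", ["acid found"]))
        assert recognize("the acid was found", lex) == []
        assert [a.span() for a in recognize("the acid found it", lex)] == [
            (4, 14, "acid found")
        ]


class TestRecognizeAll:
    def test_overlap_terms_reported_as_unknown(self):
        a = compile_lexicon(RawLexicon("chemical", ["atp", "caffeine"]))
        b = compile_lexicon(RawLexicon("protein", ["atp", "insulin"]))
        anns = recognize_all("caffeine binds atp and insulin", [(a, None), (b, None)])
        by_term = {ann.term: ann.entity_type for ann in anns}
        assert by_term == {
            "caffeine": "chemical",
            "atp": "Unknown",
            "insulin": "protein",
        }

    def test_unknown_annotations_are_not_duplicated(self):
        a = compile_lexicon(RawLexicon("a", ["atp"]))
        b = compile_lexicon(RawLexicon("b", ["atp"]))
        anns = recognize_all("atp", [(a, None), (b, None)])
        assert len(anns) == 1 and anns[0].uri is None
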