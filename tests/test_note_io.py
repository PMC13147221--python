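import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scribe_audit import note_io
from scribe_audit.note_io import (
    DEFAULT_END_MARKER,
    DEFAULT_START_MARKER,
    UNSECTIONED,
    CorpusError,
    MalformedNoteError,
    count_chars,
    count_words,
    extract_ai_note_from_emr,
    parse_note,
    read_corpus,
    tokenize,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("", []),
            ("   \n\t ", []),
            ("BP 120/80, HR 72", ["BP", "120/80,", "HR", "72"]),
            ("a\nb\tc", ["a", "b", "c"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @given(st.text(max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_regex_split_oracle(self, text):
        """Word counts agree with a one-line regex-split oracle."""
        oracle = [t for t in re.split(r"\s+", text) if t]
        assert tokenize(text) == oracle
        assert count_words(text) == len(oracle)


class TestCounts:
    def test_words_and_nonwhitespace_chars(self):
        assert count_words("a b  c") == 3
        assert count_chars("a b  c") == 3
        assert count_words("") == 0
        assert count_chars("") == 0

    def test_whitespace_inclusive_switch(self):
        assert count_chars("a b", include_whitespace=True) == 3

    @given(st.lists(st.text(alphabet="abc.", min_size=1, max_size=6), max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_word_count_equals_token_count(self, tokens):
        text = " ".join(tokens)
        assert count_words(text) == len(tokenize(text))


class TestMarkerExtraction:
    def test_between_markers(self):
        text = "HEADER\n***S***\nbody text\n***E***\ntail"
        assert extract_ai_note_from_emr(text, "***S***", "***E***") == "body text"

    def test_no_markers_means_not_ai_generated(self):
        assert extract_ai_note_from_emr("plain clinician note", "***S***", "***E***") is None

    @pytest.mark.parametrize(
        "text", ["pre ***S*** body", "body ***E*** post", "***E*** body ***S***"]
    )
    def test_single_or_reversed_marker_is_malformed(self, text):
        with pytest.raises(MalformedNoteError):
            extract_ai_note_from_emr(text, "***S***", "***E***")

    def test_empty_marker_rejected(self):
        with pytest.raises(ValueError):
            extract_ai_note_from_emr("x", "", "***E***")

    def test_marker_tokens_never_counted(self):
        body = "HOPC:\nchest pain"
        emr = f"pre\n{DEFAULT_START_MARKER}\n{body}\n{DEFAULT_END_MARKER}\npost"
        extracted = extract_ai_note_from_emr(emr)
        assert extracted == body
        assert count_words(extracted) == 3
        for marker_token in DEFAULT_START_MARKER.split():
            assert marker_token not in tokenize(extracted) or marker_token in body


class TestParseNote:
    def test_two_sections(self):
        note = parse_note("HOPC:\na b\nImpression:\nc")
        names = [s.canonical_name for s in note.sections]
        assert names == ["HOPC", "Impression"]
        hopc, imp = note.sections
        assert note.tokens[slice(*hopc.body_span)] == ("a", "b")
        assert note.tokens[slice(*imp.body_span)] == ("c",)

    def test_synonym_maps_to_canonical(self):
        note = parse_note("Plan:\nobserve overnight")
        assert note.sections[0].canonical_name == "Management Plan"

    def test_headerless_note_is_unsectioned(self):
        note = parse_note("no headers at all here")
        assert [s.canonical_name for s in note.sections] == [UNSECTIONED]
        assert note.sections[0].body_span == (0, 5)

    def test_leading_text_goes_to_unsectioned(self):
        note = parse_note("preamble words\nHOPC:\nbody")
        assert [s.canonical_name for s in note.sections] == [UNSECTIONED, "HOPC"]

    def test_header_match_is_case_insensitive_line_anchored(self):
        note = parse_note("hopc\nbody\nthe plan: inline mention")
        # "hopc" without colon still matches; an inline "plan:" phrase does not
        assert [s.canonical_name for s in note.sections] == ["HOPC"]

    def test_token_conservation(self, small_corpus):
        encounters, _ = small_corpus
        for enc in encounters[:10]:
            note = parse_note(enc.initial_note_text)
            covered = sum(
                (s.header_span[1] - s.header_span[0]) + (s.body_span[1] - s.body_span[0])
                for s in note.sections
            )
            assert covered == len(note.tokens) == count_words(enc.initial_note_text)

    def test_parse_is_idempotent_at_section_level(self):
        text = "intro\nHOPC:\na b c\nPlan:\nd e"
        note = parse_note(text)
        rebuilt = "\n".join(
            part
            for s in note.sections
            for part in ([s.header_text] if s.header_text else [])
            + [" ".join(note.tokens[slice(*s.body_span)])]
        )
        note2 = parse_note(rebuilt)
        assert [
            (s.canonical_name, note.tokens[slice(*s.body_span)]) for s in note.sections
        ] == [(s.canonical_name, note2.tokens[slice(*s.body_span)]) for s in note2.sections]


class TestReadCorpus:
    def test_count_and_round_trip(self, corpus_dir, small_corpus):
        manifest, _ = corpus_dir
        encounters, _ = small_corpus
        loaded = read_corpus(manifest)
        assert len(loaded) == len(encounters)
        by_id = {e.id: e for e in encounters}
        for enc in loaded:
            orig = by_id[enc.id]
            assert tokenize(enc.initial_note_text) == tokenize(orig.initial_note_text)
            assert enc.transcript_text == orig.transcript_text
            assert enc.role == orig.role

    def test_missing_file_names_encounter(self, corpus_dir):
        manifest, _ = corpus_dir
        victim = manifest.parent / "enc0001.emr.txt"
        victim.unlink()
        with pytest.raises(CorpusError, match="enc0001"):
            read_corpus(manifest)

    def test_corrupt_line_names_line_number(self, tmp_path):
        manifest = tmp_path / "manifest.jsonl"
        manifest.write_text('{"id": "a", "role": "trainee"}\nnot json\n')
        with pytest.raises(CorpusError, match="line 1|line 2"):
            read_corpus(manifest)

    def test_duplicate_id_rejected(self, corpus_dir):
        manifest, _ = corpus_dir
        lines = manifest.read_text().splitlines()
        manifest.write_text("\n".join(lines + [lines[0]]) + "\n")
        with pytest.raises(CorpusError, match="duplicate"):
            read_corpus(manifest)
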