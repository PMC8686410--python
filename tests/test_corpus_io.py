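"""BIO file parsing, span<->tag conversion, splitting, model sequences."""

import pytest
from hypothesis import given, settings, strategies as st

from radner.corpus_io import (
    CLS,
    PAD,
    SEP,
    CorpusFormatError,
    read_bio,
    read_bio_documents,
    spans_to_tags,
    split_long,
    tags_to_spans,
    to_model_sequence,
    write_bio,
    write_bio_documents,
)
from radner.documents import ENTITY_TYPES, AnnotatedDocument, EntitySpan

from conftest import make_doc


class TestReadBio:
    def test_two_char_sequence(self, tmp_path):
        f = tmp_path / "a.bio"
        f.write_text("头\tB-ADR\n痛\tI-ADR\n", encoding="utf-8")
        assert read_bio(f) == [("头痛", ("B-ADR", "I-ADR"))]

    def test_empty_file(self, tmp_path):
        f = tmp_path / "e.bio"
        f.write_text("", encoding="utf-8")
        assert read_bio(f) == []

    def test_unknown_label_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "b.bio"
        f.write_text("头\tB-ADR\n痛\tB-Gene\n", encoding="utf-8")
        with pytest.raises(CorpusFormatError, match="B-Gene") as exc:
            read_bio(f)
        assert exc.value.line == 2

    @pytest.mark.parametrize("bad", ["头痛\tO", "头 O", "头\tO\textra"])
    def test_malformed_line_rejected(self, tmp_path, bad):
        f = tmp_path / "c.bio"
        f.write_text(bad + "\n", encoding="utf-8")
        with pytest.raises(CorpusFormatError):
            read_bio(f)

    def test_write_read_roundtrip(self, tmp_path):
        seqs = [("头痛愈", ("B-ADR", "I-ADR", "O")), ("药", ("B-Drug",))]
        f = tmp_path / "rt.bio"
        write_bio(f, seqs)
        assert read_bio(f) == seqs

    def test_document_roundtrip_with_ids(self, tmp_path, small_corpus):
        f = tmp_path / "docs.bio"
        write_bio_documents(f, small_corpus)
        back = read_bio_documents(f)
        assert [d.doc_id for d in back] == [d.doc_id for d in small_corpus]
        assert all(
            a.text == b.text and set(a.entities) == set(b.entities)
            for a, b in zip(back, small_corpus)
        )


class TestSpanTagConversion:
    @pytest.mark.parametrize(
        "length,spans,expected",
        [
            (5, [("Drug", 1, 3)], ["O", "B-Drug", "I-Drug", "O", "O"]),
            (3, [], ["O", "O", "O"]),
            (
                5,
                [("Reason", 0, 1), ("ADR", 3, 5)],
                ["B-Reason", "O", "O", "B-ADR", "I-ADR"],
            ),
        ],
    )
    def test_spans_to_tags(self, length, spans, expected):
        doc = make_doc("d", "字" * length, spans)
        assert list(spans_to_tags(doc)) == expected

    @pytest.mark.parametrize(
        "tags,expected",
        [
            (["O", "B-Drug", "I-Drug", "O", "O"], {("Drug", 1, 3)}),
            (["I-ADR", "I-ADR"], {("ADR", 0, 2)}),
            (["B-Drug", "I-ADR"], {("Drug", 0, 1), ("ADR", 1, 2)}),
            (["B-Drug", "B-Drug"], {("Drug", 0, 1), ("Drug", 1, 2)}),
        ],
    )
    def test_tags_to_spans_including_repair(self, tags, expected):
        got = {(sp.etype, sp.start, sp.end) for sp in tags_to_spans(tags)}
        assert got == expected

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(ENTITY_TYPES),
                st.integers(0, 40),
                st.integers(1, 6),
            ),
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity_on_wellformed(self, raw):
        # build a non-overlapping span set, then encode/decode
        spans, cursor = [], 0
        for etype, gap, length in raw:
            start = cursor + gap
            spans.append(EntitySpan(start, start + length, etype))
            cursor = start + length
        doc = AnnotatedDocument("d", "字" * (cursor + 3), tuple(spans))
        assert tags_to_spans(spans_to_tags(doc)) == set(doc.entities)


class TestSplitLong:
    def test_short_doc_unchanged(self):
        doc = make_doc("d", "字" * 100, [("Drug", 5, 8)])
        assert split_long(doc, 512) == [doc]

    def test_long_doc_fragments_reconcatenate(self):
        doc = make_doc("d", "字" * 600, [])
        frags = split_long(doc, 512)
        assert len(frags) == 2
        assert all(len(f.text) <= 512 for f in frags)
        assert "".join(f.text for f in frags) == doc.text

    def test_split_point_moved_off_entity(self):
        doc = make_doc("d", "零一二三四五六甲乙丙", [("Drug", 7, 10)])
        frags = split_long(doc, 8)
        assert "".join(f.text for f in frags) == doc.text
        (holder,) = [f for f in frags if f.entities]
        sp = holder.entities[0]
        assert holder.text[sp.start : sp.end] == doc.text[7:10]

    def test_prefers_sentence_punctuation(self):
        doc = make_doc("d", "前半句。后半部分继续", [])
        frags = split_long(doc, 6)
        assert frags[0].text == "前半句。"

    def test_entity_longer_than_limit_rejected(self):
        doc = make_doc("d", "字" * 20, [("Reason", 2, 15)])
        with pytest.raises(ValueError, match="longer than"):
            split_long(doc, 10)

    def test_entity_multiset_preserved(self, small_corpus):
        for doc in small_corpus:
            frags = split_long(doc, 30)
            original = sorted(doc.entity_texts())
            split = sorted(
                pair for f in frags for pair in f.entity_texts()
            )
            assert split == original

    def test_origin_offsets_recover_original_coordinates(self, small_corpus):
        for doc in small_corpus:
            for f in split_long(doc, 25):
                for sp in f.entities:
                    shifted = sp.shifted(f.origin_offset)
                    assert doc.text[shifted.start : shifted.end] == \
                        f.text[sp.start : sp.end]


class TestToModelSequence:
    def test_basic_layout(self):
        seq = to_model_sequence(make_doc("d", "头痛", []), max_len=6)
        assert seq.tokens == (CLS, "头", "痛", SEP, PAD, PAD)
        assert seq.token_mask == (False, True, True, False, False, False)
        assert seq.origin == ("d", 0)

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            to_model_sequence(AnnotatedDocument("d", ""), max_len=8)

    def test_exact_fit_has_no_padding(self):
        seq = to_model_sequence(make_doc("d", "字" * 6, []), max_len=8)
        assert PAD not in seq.tokens
        assert seq.tokens[-1] == SEP

    def test_too_long_rejected(self):
        with pytest.raises(ValueError, match="split"):
            to_model_sequence(make_doc("d", "字" * 7, []), max_len=8)

    @pytest.mark.parametrize("n", [1, 5, 30])
    def test_length_and_mask_cardinality(self, n):
        seq = to_model_sequence(make_doc("d", "字" * n, []), max_len=64)
        assert len(seq.tokens) == 64
        assert sum(seq.token_mask) == n
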