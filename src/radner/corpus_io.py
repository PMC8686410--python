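"""Corpus reading/writing and span <-> BIO tag transformations.

File dialect: UTF-8, one ``character<TAB>tag`` pair per line, a blank line
between sequences, and an optional ``# doc_id`` comment line before each
sequence.  Tags use the BIO scheme over the closed three-type vocabulary,
giving the 7-label alphabet O, B-Reason, I-Reason, B-Drug, I-Drug, B-ADR,
I-ADR.

Model-input preparation follows the usual transformer-era conventions: a
``[CLS]`` token opens each sequence, a single ``[SEP]`` closes the real
content, and ``[PAD]`` tokens fill the sequence to a fixed maximum length
(default 512).  Narratives longer than the maximum content length are split
into fragments, preferentially at Chinese sentence-final punctuation and
never through an entity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .documents import ENTITY_TYPES, AnnotatedDocument, EntitySpan

#: BIO label alphabet.  "O" first, so the all-ties Viterbi path decodes to
#: all-outside.
TAGS: tuple[str, ...] = ("O",) + tuple(
    f"{p}-{t}" for t in ENTITY_TYPES for p in ("B", "I")
)
TAG_TO_INDEX: dict[str, int] = {t: i for i, t in enumerate(TAGS)}

CLS, SEP, PAD = "[CLS]", "[SEP]", "[PAD]"
CONTROL_TOKENS = (CLS, SEP, PAD)

#: Chinese sentence-final punctuation used as preferred split points.
SENTENCE_FINAL = "。？！；"  # 。 ？ ！ ；


class CorpusFormatError(ValueError):
    """Raised for malformed BIO files, with a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class ModelSequence:
    """A fragment prepared for the tagger: control tokens added, padded.

    ``tokens`` holds single characters plus the [CLS]/[SEP]/[PAD] control
    strings; ``token_mask`` is True exactly on the real-character positions;
    ``origin`` is ``(doc_id, offset of the first real character)`` in
    whole-narrative coordinates.
    """

    tokens: tuple[str, ...]
    token_mask: tuple[bool, ...]
    origin: tuple[str, int]

    def real_chars(self) -> tuple[str, ...]:
        return tuple(t for t, m in zip(self.tokens, self.token_mask) if m)


# ---------------------------------------------------------------------------
# BIO file I/O


def read_bio(path: str | Path) -> list[tuple[str, tuple[str, ...]]]:
    """Read a two-column BIO file into (text, tags) pairs.

    Returns one ``(character string, tag tuple)`` pair per sequence.  Raises
    :class:`CorpusFormatError` (with line number) for malformed lines,
    labels outside the closed alphabet, or empty sequences delimited by
    comment lines.
    """
    seqs: list[tuple[str, tuple[str, ...]]] = []
    chars: list[str] = []
    tags: list[str] = []
    pending_comment_line: int | None = None

    def flush(line_no: int) -> None:
        nonlocal pending_comment_line
        if chars:
            seqs.append(("".join(chars), tuple(tags)))
            chars.clear()
            tags.clear()
            pending_comment_line = None
        elif pending_comment_line is not None:
            raise CorpusFormatError(
                "document comment with no sequence", pending_comment_line
            )

    text = Path(path).read_text(encoding="utf-8")
    for i, line in enumerate(text.split("\n"), start=1):
        if line == "":
            flush(i)
            continue
        if line.startswith("#"):
            if chars:
                raise CorpusFormatError("comment inside a sequence", i)
            pending_comment_line = i
            continue
        parts = line.split("\t")
        if len(parts) != 2 or len(parts[0]) != 1:
            raise CorpusFormatError(f"malformed line {line!r}", i)
        ch, tag = parts
        if tag not in TAG_TO_INDEX:
            raise CorpusFormatError(f"unknown tag label {tag!r}", i)
        chars.append(ch)
        tags.append(tag)
    flush(len(text.split("\n")) + 1)
    return seqs


def write_bio(
    path: str | Path, seqs: Iterable[tuple[str, Sequence[str]]]
) -> None:
    """Write (text, tags) pairs as a two-column BIO file (round-trips with
    :func:`read_bio` bit-exactly)."""
    lines: list[str] = []
    for text, tags in seqs:
        if len(text) != len(tags):
            raise ValueError("text/tags length mismatch")
        for ch, tag in zip(text, tags):
            if tag not in TAG_TO_INDEX:
                raise ValueError(f"unknown tag label {tag!r}")
            lines.append(f"{ch}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_bio_documents(path: str | Path) -> list[AnnotatedDocument]:
    """Read a BIO file as :class:`AnnotatedDocument` objects.

    Doc ids come from ``# doc_id`` comments when present, else the 0-based
    sequence index as a string.
    """
    docs: list[AnnotatedDocument] = []
    # second pass purely to attach "# doc_id" comments to their sequences
    ids: list[str | None] = []
    current_id: str | None = None
    in_seq = False
    for line in Path(path).read_text(encoding="utf-8").split("\n"):
        if line.startswith("#"):
            current_id = line[1:].strip()
        elif line == "":
            if in_seq:
                ids.append(current_id)
                current_id = None
                in_seq = False
        else:
            in_seq = True
    if in_seq:
        ids.append(current_id)

    for i, (text, tags) in enumerate(read_bio(path)):
        doc_id = ids[i] if i < len(ids) and ids[i] else str(i)
        docs.append(
            AnnotatedDocument(doc_id, text, tuple(sorted(tags_to_spans(tags))))
        )
    return docs


def write_bio_documents(
    path: str | Path, docs: Iterable[AnnotatedDocument]
) -> None:
    """Write documents as a BIO file with ``# doc_id`` comments."""
    lines: list[str] = []
    for doc in docs:
        lines.append(f"# {doc.doc_id}")
        tags = spans_to_tags(doc)
        for ch, tag in zip(doc.text, tags):
            lines.append(f"{ch}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_plain_texts(path: str | Path) -> list[str]:
    """Plain-text prediction input: one narrative per line, UTF-8."""
    return [
        line
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


# ---------------------------------------------------------------------------
# span <-> tag conversion


def spans_to_tags(doc: AnnotatedDocument) -> tuple[str, ...]:
    """Encode a document's spans as BIO labels (B-T at span start, I-T inside)."""
    tags = ["O"] * len(doc.text)
    for sp in doc.entities:  # validated non-overlapping by the document
        tags[sp.start] = f"B-{sp.etype}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.etype}"
    return tuple(tags)


def tags_to_spans(tags: Sequence[str]) -> set[EntitySpan]:
    """Decode BIO labels to spans; total on ill-formed input.

    Repair rule (conlleval convention): a stray ``I-T`` not preceded by a
    ``B-T``/``I-T`` of the same type opens a new entity, as if it were
    ``B-T``.
    """
    spans: set[EntitySpan] = set()
    start: int | None = None
    cur_type: str | None = None
    for i, tag in enumerate(tags):
        if tag not in TAG_TO_INDEX:
            raise ValueError(f"unknown tag label {tag!r}")
        if tag == "O":
            prefix, etype = "O", None
        else:
            prefix, etype = tag.split("-", 1)
        continues = prefix == "I" and cur_type == etype and start is not None
        if not continues:
            if start is not None:
                spans.add(EntitySpan(start, i, cur_type))
                start, cur_type = None, None
            if prefix in ("B", "I"):  # stray I- opens a new entity
                start, cur_type = i, etype
    if start is not None:
        spans.add(EntitySpan(start, len(tags), cur_type))
    return spans


# ---------------------------------------------------------------------------
# length-limited splitting and model-sequence preparation


def split_long(
    doc: AnnotatedDocument, max_content_len: int
) -> list[AnnotatedDocument]:
    """Split a narrative into fragments of at most ``max_content_len`` chars.

    Split points prefer the position just after the last Chinese
    sentence-final punctuation mark (。？！；) inside the allowed window and
    are shifted left so that no entity is bisected; a hard split at the
    limit is the fallback.  Fragment texts concatenate back to ``doc.text``
    and every entity lands intact in exactly one fragment (offsets shifted;
    ``origin_offset`` records the fragment's position in the original).
    """
    if max_content_len < 2:
        raise ValueError("max_content_len must be >= 2")
    too_long = [sp for sp in doc.entities if sp.length > max_content_len]
    if too_long:
        raise ValueError(
            f"{doc.doc_id}: entity {too_long[0]} longer than "
            f"max_content_len={max_content_len}"
        )
    if len(doc.text) <= max_content_len:
        return [doc]

    fragments: list[AnnotatedDocument] = []
    offset = 0
    n = len(doc.text)
    part = 0
    while n - offset > max_content_len:
        window = doc.text[offset : offset + max_content_len]
        cut = max((window.rfind(p) for p in SENTENCE_FINAL), default=-1)
        split_at = offset + cut + 1 if cut >= 0 else offset + max_content_len
        split_at = _avoid_entity(doc, split_at)
        if split_at <= offset:  # punctuation choice collapsed; hard split
            split_at = _avoid_entity(doc, offset + max_content_len)
        assert offset < split_at <= offset + max_content_len
        fragments.append(_fragment(doc, offset, split_at, part))
        offset = split_at
        part += 1
    fragments.append(_fragment(doc, offset, n, part))
    return fragments


def _avoid_entity(doc: AnnotatedDocument, pos: int) -> int:
    """Shift a split point left to the start of any entity it would bisect."""
    for sp in doc.entities:
        if sp.start < pos < sp.end:
            return sp.start
    return pos


def _fragment(
    doc: AnnotatedDocument, start: int, end: int, part: int
) -> AnnotatedDocument:
    ents = tuple(
        sp.shifted(-start)
        for sp in doc.entities
        if start <= sp.start and sp.end <= end
    )
    doc_id = doc.doc_id if part == 0 and end == len(doc.text) else f"{doc.doc_id}#{part}"
    return AnnotatedDocument(
        doc_id, doc.text[start:end], ents, origin_offset=doc.origin_offset + start
    )


def to_model_sequence(
    fragment: AnnotatedDocument, max_len: int = 512
) -> ModelSequence:
    """Wrap a fragment as ``[CLS] text [SEP] [PAD]...`` of length ``max_len``.

    The token mask is True exactly on the real-character positions.  Empty
    fragments and fragments longer than ``max_len - 2`` are rejected (split
    first).
    """
    n = len(fragment.text)
    if n == 0:
        raise ValueError("empty fragment cannot form a model sequence")
    if n > max_len - 2:
        raise ValueError(
            f"fragment length {n} exceeds max_len-2={max_len - 2}; "
            "apply split_long first"
        )
    tokens = (CLS,) + tuple(fragment.text) + (SEP,) + (PAD,) * (max_len - n - 2)
    mask = (False,) + (True,) * n + (False,) * (max_len - n - 1)
    return ModelSequence(tokens, mask, (fragment.doc_id, fragment.origin_offset))
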