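"""Core document containers for ADE-narrative entity annotation.

An :class:`AnnotatedDocument` is a sequence of Unicode characters (the
free-text section of a Chinese adverse-drug-event report) together with a
set of typed, non-overlapping entity spans.  Offsets are 0-based, half-open
character offsets; the character — not the word — is the token unit
throughout, as is standard for Chinese clinical NER.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Closed entity-type vocabulary: the indication/symptom behind the drug use,
#: the drug itself (generic / trade name / abbreviation), and the adverse
#: drug reaction.
ENTITY_TYPES: tuple[str, ...] = ("Reason", "Drug", "ADR")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity occupying the half-open character range [start, end)."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(
                f"unknown entity type {self.etype!r}; expected one of {ENTITY_TYPES}"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, delta: int) -> "EntitySpan":
        return EntitySpan(self.start + delta, self.end + delta, self.etype)


@dataclass(frozen=True)
class AnnotatedDocument:
    """A character sequence plus typed, non-overlapping entity spans.

    Parameters
    ----------
    doc_id:
        Opaque identifier; evaluation pairs gold and predicted documents by it.
    text:
        The narrative as a plain string (one character per token position).
    entities:
        Entity spans; validated to lie in bounds and to be mutually disjoint
        (nested or crossing spans are rejected).
    origin_offset:
        Offset of this document's first character inside the whole narrative
        it was split from; 0 for unsplit documents.  Bookkeeping only — not
        part of document identity.
    """

    doc_id: str
    text: str
    entities: tuple[EntitySpan, ...] = ()
    origin_offset: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        spans = tuple(sorted(self.entities))
        object.__setattr__(self, "entities", spans)
        n = len(self.text)
        prev_end = 0
        for sp in spans:
            if sp.end > n:
                raise ValueError(
                    f"{self.doc_id}: span {sp} exceeds text length {n}"
                )
            if sp.start < prev_end:
                raise ValueError(
                    f"{self.doc_id}: overlapping entity spans at offset {sp.start}"
                )
            prev_end = sp.end

    def __len__(self) -> int:
        return len(self.text)

    def entity_texts(self) -> list[tuple[str, str]]:
        """(etype, surface string) pairs, in offset order."""
        return [(sp.etype, self.text[sp.start : sp.end]) for sp in self.entities]

    def span_set(self) -> set[tuple[str, int, int]]:
        """Hashable (etype, start, end) triples, for strict-match scoring."""
        return {(sp.etype, sp.start, sp.end) for sp in self.entities}
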