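"""Shared domain types and span arithmetic used by every pipeline stage.

All offsets are 0-based, half-open, counted in characters of the decoded
text (never bytes).  Annotations never hold a copy of the document text;
surface strings are validated against their spans at construction time so
annotations cannot drift from the text they describe.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class TokenTag(enum.Enum):
    WORD = "WORD"
    CHEMICAL = "CHEMICAL"
    SERIES_LETTER = "SERIES_LETTER"
    LABEL_NUMBER = "LABEL_NUMBER"
    CONJ_AND = "CONJ_AND"
    CONJ_TO = "CONJ_TO"
    DASH = "DASH"
    PUNCT = "PUNCT"
    ORGANISM_PART = "ORGANISM_PART"
    ASSAY = "ASSAY"
    OTHER = "OTHER"


class EntityType(enum.Enum):
    COMPOUND = "COMPOUND"
    ORGANISM = "ORGANISM"
    ASSAY = "ASSAY"


class OrganismRank(enum.Enum):
    GENUS_ONLY = "GENUS_ONLY"
    SPECIES = "SPECIES"


@dataclass(frozen=True, order=True)
class TextSpan:
    """Half-open character interval [start, end) into a document text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end


def span_text(document_text: str, span: TextSpan) -> str:
    """Return the exact substring of *document_text* covered by *span*.

    Raises IndexError when the span reaches past the end of the text.
    """
    if span.end > len(document_text):
        raise IndexError(
            f"span [{span.start}, {span.end}) out of bounds for text of "
            f"length {len(document_text)}"
        )
    return document_text[span.start : span.end]


@dataclass
class Token:
    text: str
    span: TextSpan
    tag: TokenTag = TokenTag.WORD

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("token text must be non-empty")
        if len(self.text) != len(self.span):
            raise ValueError(
                f"token text {self.text!r} does not fit span "
                f"[{self.span.start}, {self.span.end})"
            )


@dataclass
class EntityAnnotation:
    entity_type: EntityType
    surface: str
    span: TextSpan
    canonical: str
    source_id: str = ""
    rank: Optional[OrganismRank] = None

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("canonical form must be non-empty")


@dataclass
class StructurePayload:
    structure_id: str
    smiles: str
    mol_path: Optional[str] = None


@dataclass
class CompoundEntity:
    """One individual compound, possibly expanded from a coordinated chunk.

    ``base_name`` is the singular head (``"drechslerine"``), ``series`` the
    distinguishing letter within a compound family, and ``label`` the
    reference number used in text and beside structure drawings.
    """

    base_name: str
    series: Optional[str] = None
    label: Optional[str] = None
    span: Optional[TextSpan] = None
    structure: Optional[StructurePayload] = None

    @property
    def display_name(self) -> str:
        if self.series:
            return f"{self.base_name} {self.series}"
        return self.base_name


@dataclass
class ProducesRelation:
    """A compound was isolated/extracted/... from a source organism."""

    compound_ref: str
    organism: EntityAnnotation
    trigger_verb: str
    sentence_span: TextSpan
    compound: Optional[CompoundEntity] = None

    def __post_init__(self) -> None:
        if self.organism.entity_type is not EntityType.ORGANISM:
            raise ValueError("relation target must be an ORGANISM annotation")


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    entities: list[EntityAnnotation] = field(default_factory=list)
    compounds: list[CompoundEntity] = field(default_factory=list)
    relations: list[ProducesRelation] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Check the core invariants: ordered non-overlapping tokens and
        every annotation surface equal to its span's text."""
        prev_end = 0
        for tok in self.tokens:
            if tok.span.start < prev_end:
                raise ValueError(f"token {tok.text!r} overlaps its predecessor")
            if span_text(self.text, tok.span) != tok.text:
                raise ValueError(f"token {tok.text!r} does not match its span")
            prev_end = tok.span.end
        for ent in self.entities:
            if span_text(self.text, ent.span) != ent.surface:
                raise ValueError(
                    f"annotation surface {ent.surface!r} does not match span"
                )
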