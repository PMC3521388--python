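"""Coordination resolution: expand compound groups into individual compounds.

Abstracts compress whole compound families into one chunk — "drechslerines
C-G (6-10)" names five compounds, drechslerine C (6) through drechslerine
G (10).  A small state machine walks the tagged token stream, accumulating
the chemical name, the series letters, and the reference labels of the
current chunk, expanding letter and number ranges ("A-C" -> A, B, C;
"1-3" -> 1, 2, 3, with "to" behaving as an inclusive range and "and" as
enumeration), and emits one :class:`~chemlit.model.CompoundEntity` per
series item, pairing series and labels positionally.

Only pure-digit labels participate in range expansion; primed or Roman
labels pass through label recognition elsewhere but are not expanded here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import CompoundEntity, TextSpan, Token, TokenTag
from .tokenizer import is_generic_head


class RangeKind(enum.Enum):
    LETTER = "LETTER"
    NUMBER = "NUMBER"


class RangeError(ValueError):
    pass


@dataclass(frozen=True)
class RangeSpec:
    start: str
    end: str
    kind: RangeKind


def expand_range(
    spec: RangeSpec, config: PipelineConfig = DEFAULT_CONFIG
) -> list[str]:
    """Inclusive consecutive sequence from start to end ("A-C" -> A, B, C).

    Inverted ranges and expansions past the configured cap (guards against
    OCR garbage like "1-1000") raise :class:`RangeError`.
    """
    if spec.kind is RangeKind.LETTER:
        lo, hi = ord(spec.start.upper()), ord(spec.end.upper())
        if lo > hi:
            raise RangeError(f"inverted letter range {spec.start}-{spec.end}")
        if hi - lo + 1 > config.letter_range_cap:
            raise RangeError(f"letter range {spec.start}-{spec.end} exceeds cap")
        return [chr(c) for c in range(lo, hi + 1)]
    lo, hi = int(spec.start), int(spec.end)
    if lo > hi:
        raise RangeError(f"inverted number range {spec.start}-{spec.end}")
    if hi - lo + 1 > config.number_range_cap:
        raise RangeError(
            f"number range {spec.start}-{spec.end} exceeds cap "
            f"({config.number_range_cap})"
        )
    return [str(v) for v in range(lo, hi + 1)]


def singularize_head(plural_name: str, distributing: bool) -> str:
    """Strip the plural 's' from a chunk head when distributing over a
    series ("multiplolides A and B" -> head "multiplolide")."""
    if distributing and plural_name.endswith("s") and not plural_name.endswith("ss"):
        return plural_name[:-1]
    return plural_name


_PURE_DIGITS = str.isdigit


def _strip_label(text: str) -> str:
    return text.strip("()").rstrip("'’")


class _State(enum.Enum):
    TEXT = enum.auto()
    NAME = enum.auto()
    SERIES = enum.auto()
    LABEL = enum.auto()


@dataclass
class _Chunk:
    name_tokens: list[str]
    series: list[str]
    labels: list[str]
    start: int
    end: int

    @property
    def name(self) -> str:
        return " ".join(self.name_tokens)


def resolve(
    tokens: list[Token],
    config: PipelineConfig = DEFAULT_CONFIG,
    warnings: list[str] | None = None,
) -> list[CompoundEntity]:
    """Run the coordination state machine over a tagged token stream.

    Emits one entity per series item (positionally paired with labels),
    one per label for series-less chunks, and a single entity for a bare
    chemical name.  Series/label count mismatches emit entities for the
    shorter list and append a warning instead of silently dropping data.
    """
    if warnings is None:
        warnings = []
    entities: list[CompoundEntity] = []
    state = _State.TEXT
    chunk: _Chunk | None = None
    pending_range = False  # a DASH or "to" awaiting its range end

    def close() -> None:
        nonlocal state, chunk, pending_range
        if chunk is not None:
            entities.extend(_emit(chunk, warnings))
        state, chunk, pending_range = _State.TEXT, None, False

    for tok in tokens:
        tag = tok.tag
        if state is _State.TEXT:
            if tag is TokenTag.CHEMICAL:
                chunk = _Chunk([tok.text], [], [], tok.span.start, tok.span.end)
                state = _State.NAME
            continue

        assert chunk is not None
        if tag is TokenTag.PUNCT and tok.text in ("(", ")", ","):
            continue  # transparent inside a chunk

        if state is _State.NAME:
            if tag is TokenTag.CHEMICAL:
                chunk.name_tokens.append(tok.text)
                chunk.end = tok.span.end
            elif tag is TokenTag.SERIES_LETTER:
                chunk.series.append(tok.text.upper())
                chunk.end = tok.span.end
                state = _State.SERIES
            elif tag is TokenTag.LABEL_NUMBER:
                _collect_label(chunk, tok, False, warnings, config)
                state = _State.LABEL
            else:
                close()
        elif state is _State.SERIES:
            if tag in (TokenTag.DASH, TokenTag.CONJ_TO):
                pending_range = True
            elif tag is TokenTag.CONJ_AND:
                pending_range = False
            elif tag is TokenTag.SERIES_LETTER:
                _collect_series(chunk, tok, pending_range, warnings, config)
                pending_range = False
                chunk.end = tok.span.end
            elif tag is TokenTag.LABEL_NUMBER:
                _collect_label(chunk, tok, False, warnings, config)
                pending_range = False
                state = _State.LABEL
            elif tag is TokenTag.CHEMICAL:
                close()
                chunk = _Chunk([tok.text], [], [], tok.span.start, tok.span.end)
                state = _State.NAME
            else:
                close()
        elif state is _State.LABEL:
            if tag in (TokenTag.DASH, TokenTag.CONJ_TO):
                pending_range = True
            elif tag is TokenTag.CONJ_AND:
                pending_range = False
            elif tag is TokenTag.LABEL_NUMBER:
                _collect_label(chunk, tok, pending_range, warnings, config)
                pending_range = False
            elif tag is TokenTag.SERIES_LETTER:
                # "A (1) and B (2)": a letter after labels reopens the series
                _collect_series(chunk, tok, False, warnings, config)
                chunk.end = tok.span.end
                state = _State.SERIES
            elif tag is TokenTag.CHEMICAL:
                close()
                chunk = _Chunk([tok.text], [], [], tok.span.start, tok.span.end)
                state = _State.NAME
            else:
                close()
    close()
    return entities


def _collect_series(
    chunk: _Chunk,
    tok: Token,
    as_range: bool,
    warnings: list[str],
    config: PipelineConfig,
) -> None:
    letter = tok.text.upper()
    if as_range and chunk.series:
        try:
            expanded = expand_range(
                RangeSpec(chunk.series[-1], letter, RangeKind.LETTER), config
            )
        except RangeError as exc:
            warnings.append(str(exc))
            chunk.series.append(letter)
            return
        chunk.series.extend(expanded[1:])
    else:
        chunk.series.append(letter)


def _collect_label(
    chunk: _Chunk,
    tok: Token,
    as_range: bool,
    warnings: list[str],
    config: PipelineConfig,
) -> None:
    label = _strip_label(tok.text)
    if not _PURE_DIGITS(label):
        warnings.append(f"non-numeric label {tok.text!r} not expanded")
        return
    if as_range and chunk.labels:
        try:
            expanded = expand_range(
                RangeSpec(chunk.labels[-1], label, RangeKind.NUMBER), config
            )
        except RangeError as exc:
            warnings.append(str(exc))
            chunk.labels.append(label)
            return
        chunk.labels.extend(expanded[1:])
    else:
        chunk.labels.append(label)


def _emit(chunk: _Chunk, warnings: list[str]) -> list[CompoundEntity]:
    span = TextSpan(chunk.start, chunk.end)
    name = chunk.name
    if chunk.series:
        distributing = len(chunk.series) >= 2
        head = _singularize_name(name, distributing)
        n = min(len(chunk.series), len(chunk.labels)) if chunk.labels else len(chunk.series)
        if chunk.labels and len(chunk.series) != len(chunk.labels):
            warnings.append(
                f"series/label count mismatch in chunk {name!r}: "
                f"{len(chunk.series)} series vs {len(chunk.labels)} labels"
            )
        out = []
        for i, letter in enumerate(chunk.series):
            if chunk.labels and i >= n:
                break
            label = chunk.labels[i] if chunk.labels else None
            out.append(CompoundEntity(head, series=letter, label=label, span=span))
        return out
    if chunk.labels:
        head = _singularize_name(name, len(chunk.labels) >= 2)
        return [
            CompoundEntity(head, label=label, span=span) for label in chunk.labels
        ]
    if all(is_generic_head(w) for w in chunk.name_tokens):
        return []  # bare "compounds" with no series or label names nothing
    return [CompoundEntity(name, span=span)]


def _singularize_name(name: str, distributing: bool) -> str:
    words = name.split(" ")
    words[-1] = singularize_head(words[-1], distributing)
    return " ".join(words)
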