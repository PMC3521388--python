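"""Chemistry-aware tokenization and baseline chemical-token tagging.

Tokenization is whitespace-first, then repaired for chemistry: a run
with internal hyphens, commas, parentheses, or primes attached to
alphanumerics ("2-Amino-2-(hydroxymethyl)-1,3-propanediol") stays one
token; trailing sentence punctuation is split off unless the token is a
scientific-name abbreviation ("sp.", "spec.", "spp.", or a genus initial
like "P."); and series/label ranges ("A-E", "(6-10)") are split around
their dash so the coordination state machine sees the range structure.

The chemical tagger is a transparent gazetteer + morphology baseline: a
pluggable stand-in honouring the same tag-stream contract as a trained
chemical named-entity recognizer.
"""

from __future__ import annotations

import re

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import TextSpan, Token, TokenTag

#: Trailing characters split off as their own punctuation tokens.
_TRAILING_PUNCT = ".,;:!?"

_ABBREV_RE = re.compile(r"(?:[A-Z]|sp|spec|spp)\.$")

_LETTER_RANGE_RE = re.compile(r"^([A-Z])(-)([A-Z])$")
_NUMBER_RANGE_RE = re.compile(r"^(\()?(\d+['’]?)(-)(\d+['’]?)(\))?$")

_LABEL_RE = re.compile(r"^\(?\d+['’]?\)?$")
_SINGLE_CAPITAL_RE = re.compile(r"^[A-Z]$")


def _is_abbreviation(piece: str) -> bool:
    """True for tokens whose final period belongs to the token itself."""
    return bool(_ABBREV_RE.fullmatch(piece))


def tokenize(text: str) -> list[Token]:
    """Split *text* into span-anchored tokens.

    Deterministic and single-pass; concatenating token surfaces with the
    original inter-token gaps reconstructs the input exactly.
    """
    tokens: list[Token] = []
    for match in re.finditer(r"\S+", text):
        _split_chunk(match.group(), match.start(), tokens)
    return tokens


def _split_chunk(chunk: str, offset: int, out: list[Token]) -> None:
    if chunk == "-":
        out.append(Token(chunk, TextSpan(offset, offset + 1), TokenTag.DASH))
        return

    # Peel trailing sentence punctuation, protecting abbreviations.
    trailing: list[tuple[str, int]] = []
    while len(chunk) > 1 and chunk[-1] in _TRAILING_PUNCT:
        if chunk[-1] == "." and _is_abbreviation(chunk):
            break
        trailing.append((chunk[-1], offset + len(chunk) - 1))
        chunk = chunk[:-1]

    _split_ranges(chunk, offset, out)
    for ch, pos in reversed(trailing):
        out.append(Token(ch, TextSpan(pos, pos + 1), TokenTag.PUNCT))


def _split_ranges(piece: str, offset: int, out: list[Token]) -> None:
    """Split series ranges (A-E) and label ranges ((6-10)) at the dash;
    any other hyphenated run stays a single token."""
    m = _LETTER_RANGE_RE.fullmatch(piece)
    if m:
        out.append(Token(piece[0], TextSpan(offset, offset + 1)))
        out.append(Token("-", TextSpan(offset + 1, offset + 2), TokenTag.DASH))
        out.append(Token(piece[2], TextSpan(offset + 2, offset + 3)))
        return
    m = _NUMBER_RANGE_RE.fullmatch(piece)
    if m:
        pos = offset
        for i, part in enumerate(m.groups()):
            if part is None:
                continue
            tag = TokenTag.WORD
            if part in "()":
                tag = TokenTag.PUNCT
            elif part == "-":
                tag = TokenTag.DASH
            out.append(Token(part, TextSpan(pos, pos + len(part)), tag))
            pos += len(part)
        return
    tag = TokenTag.PUNCT if all(not ch.isalnum() for ch in piece) else TokenTag.WORD
    out.append(Token(piece, TextSpan(offset, offset + len(piece)), tag))


def split_sentences(tokens: list[Token]) -> list[list[Token]]:
    """Group tokens into sentences at standalone '.', '!', '?' tokens.

    Abbreviation periods never split: they are part of their token, so no
    standalone terminator exists at those positions.
    """
    sentences: list[list[Token]] = []
    current: list[Token] = []
    for tok in tokens:
        current.append(tok)
        if tok.tag is TokenTag.PUNCT and tok.text in (".", "!", "?"):
            sentences.append(current)
            current = []
    if current:
        sentences.append(current)
    return sentences


_GENERIC_HEADS = frozenset({"compound", "compounds"})


def is_generic_head(word: str) -> bool:
    """True for the literal chunk heads "compound"/"compounds"."""
    return word.lower() in _GENERIC_HEADS


def tag_chemicals(
    tokens: list[Token],
    gazetteer: set[str] | frozenset[str] = frozenset(),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[Token]:
    """Assign CHEMICAL / SERIES_LETTER / LABEL_NUMBER / CONJ / DASH tags
    in place and return the token list.

    A token is CHEMICAL when it (i) appears in the gazetteer
    (case-insensitive, optional plural 's'), (ii) bears a chemical suffix
    (-olide, -mycin, -ol, ...) and is long enough, or (iii) has the shape
    of a systematic name: letters interleaved with at least two of
    digit/hyphen/comma/parenthesis.  A single capital letter is a
    SERIES_LETTER only in chemical context (after a chemical name or
    within a running series enumeration).
    """
    folded_gaz = {term.lower() for term in gazetteer}
    in_series_context = False
    for tok in tokens:
        if tok.tag in (TokenTag.PUNCT, TokenTag.DASH):
            if tok.tag is TokenTag.PUNCT and tok.text not in ("(", ")", ","):
                in_series_context = False
            continue
        lower = tok.text.lower()
        if lower == "and":
            tok.tag = TokenTag.CONJ_AND
            continue
        if lower == "to":
            tok.tag = TokenTag.CONJ_TO
            continue
        if _LABEL_RE.fullmatch(tok.text):
            tok.tag = TokenTag.LABEL_NUMBER
            continue
        if _SINGLE_CAPITAL_RE.fullmatch(tok.text):
            if in_series_context:
                tok.tag = TokenTag.SERIES_LETTER
                continue
            tok.tag = TokenTag.WORD
            in_series_context = False
            continue
        if _is_chemical(lower, tok.text, folded_gaz, config):
            tok.tag = TokenTag.CHEMICAL
            in_series_context = True
            continue
        tok.tag = TokenTag.WORD
        in_series_context = False
    return tokens


def _is_chemical(
    lower: str, raw: str, gazetteer: set[str], config: PipelineConfig
) -> bool:
    if lower in gazetteer or (lower.endswith("s") and lower[:-1] in gazetteer):
        return True
    if lower in _GENERIC_HEADS:
        return True
    if len(raw) >= config.min_suffix_token_len and re.fullmatch(r"[A-Za-z-]+", raw):
        for suffix in config.chemical_suffixes:
            if lower.endswith(suffix) or lower.endswith(suffix + "s"):
                return True
    # Systematic-name shape: letters interleaved with structure punctuation.
    n_special = sum(1 for ch in raw if ch.isdigit() or ch in "-,()")
    has_letter = any(ch.isalpha() for ch in raw)
    return has_letter and n_special >= 2
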