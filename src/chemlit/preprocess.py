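"""Repair PDF-extraction artifacts and pick the text source for a document.

PDF-to-text conversion of chemistry papers habitually renders the hyphen
in series and label ranges ("Aigialomycins A-E (2-6)") as an unknown
character ``?``.  ``repair_ocr_dashes`` undoes exactly that damage: a
``?`` flanked on both immediate sides by alphanumerics becomes ``-``;
every other ``?`` (genuine questions, trailing marks) is preserved.

When a BibTeX record is available its abstract field is preferred over
extracted full text, which tends to arrive with headers, footers, and
broken paragraphs mixed in.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class BibRecord:
    cite_key: str
    title: str = ""
    authors: str = ""
    year: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.cite_key:
            raise ValueError("cite_key must be non-empty")


def repair_ocr_dashes(text: str) -> str:
    """Replace ``?`` with ``-`` wherever both immediate neighbours are
    alphanumeric ([A-Za-z0-9]); leave all other ``?`` untouched.

    Idempotent: the replacement character is never itself a trigger.
    """
    if "?" not in text:
        return text
    chars = list(text)
    for i, ch in enumerate(chars):
        if ch != "?":
            continue
        if 0 < i < len(chars) - 1 and _is_alnum_ascii(text[i - 1]) and _is_alnum_ascii(text[i + 1]):
            chars[i] = "-"
    return "".join(chars)


def _is_alnum_ascii(ch: str) -> bool:
    return ("a" <= ch <= "z") or ("A" <= ch <= "Z") or ("0" <= ch <= "9")


class BibtexParseError(ValueError):
    pass


def parse_bibtex(bibtex_text: str) -> list[BibRecord]:
    """Parse BibTeX entries into records, in file order.

    Fields are keyed case-insensitively; one level of surrounding braces
    or quotes is stripped from values.  LaTeX escapes inside values are
    passed through unmodified.  Unbalanced braces raise
    :class:`BibtexParseError` naming the offending entry.
    """
    records: list[BibRecord] = []
    i = 0
    n = len(bibtex_text)
    while i < n:
        at = bibtex_text.find("@", i)
        if at < 0:
            break
        brace = bibtex_text.find("{", at)
        if brace < 0:
            break
        entry_type = bibtex_text[at + 1 : brace].strip().lower()
        if entry_type in ("comment", "preamble"):
            i = _skip_balanced(bibtex_text, brace, entry_name="@" + entry_type)
            continue
        end = _skip_balanced(bibtex_text, brace, entry_name="@" + entry_type)
        body = bibtex_text[brace + 1 : end - 1]
        comma = body.find(",")
        if comma < 0:
            cite_key, fields_src = body.strip(), ""
        else:
            cite_key, fields_src = body[:comma].strip(), body[comma + 1 :]
        if entry_type == "string":
            i = end
            continue
        fields = _parse_fields(fields_src, cite_key or "@" + entry_type)
        records.append(
            BibRecord(
                cite_key=cite_key or f"entry{len(records) + 1}",
                title=fields.get("title", ""),
                authors=fields.get("author", ""),
                year=fields.get("year", ""),
                abstract=fields.get("abstract", ""),
            )
        )
        i = end
    return records


def _skip_balanced(text: str, open_brace: int, entry_name: str) -> int:
    """Return index one past the brace matching text[open_brace]."""
    depth = 0
    for j in range(open_brace, len(text)):
        if text[j] == "{":
            depth += 1
        elif text[j] == "}":
            depth -= 1
            if depth == 0:
                return j + 1
    raise BibtexParseError(f"unbalanced braces in entry {entry_name}")


def _parse_fields(src: str, cite_key: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    i = 0
    n = len(src)
    while i < n:
        eq = src.find("=", i)
        if eq < 0:
            break
        name = src[i:eq].strip().strip(",").strip().lower()
        j = eq + 1
        while j < n and src[j] in " \t\r\n":
            j += 1
        if j >= n:
            break
        if src[j] == "{":
            end = _skip_balanced(src, j, cite_key)
            value = src[j + 1 : end - 1]
            i = end
        elif src[j] == '"':
            end = src.find('"', j + 1)
            if end < 0:
                raise BibtexParseError(f"unterminated quoted value in entry {cite_key}")
            value = src[j + 1 : end]
            i = end + 1
        else:
            end = j
            while end < n and src[end] not in ",\n":
                end += 1
            value = src[j:end].strip()
            i = end
        if name:
            fields[name] = " ".join(value.split())
        while i < n and src[i] in " \t\r\n,":
            i += 1
    return fields


class UnusableInputError(ValueError):
    pass


def select_text_source(
    plain_text: str | None = None,
    records: list[BibRecord] | None = None,
) -> tuple[str, str]:
    """Choose the document text: BibTeX abstract when present, else plain text.

    Returns ``(doc_id, repaired_text)``; the chosen text is passed through
    :func:`repair_ocr_dashes`.
    """
    if records:
        for rec in records:
            if rec.abstract.strip():
                return rec.cite_key, repair_ocr_dashes(rec.abstract)
    if plain_text is not None:
        return "doc", repair_ocr_dashes(plain_text)
    raise UnusableInputError(
        "no usable text: supply plain text or a BibTeX record with a non-empty abstract"
    )
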