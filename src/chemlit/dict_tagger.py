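"""Dictionary-based organism and assay tagging.

Organisms are recognized from configurable taxonomic dictionaries (ITIS /
LPSN / Catalogue-of-Life shaped: canonical name, identifier, optional
phylum/family/genus/species ranks, variant synonyms) in three passes:

1. full variant strings, longest match first, case-insensitive;
2. a document-scoped re-scan for abbreviated scientific names ("E. coli")
   of every variant actually detected in pass 1;
3. genus-level mentions with an unspecified-species marker
   ("Penicillium sp." / "spec." / "spp."), annotated at genus rank.

Assay terms (single-word bioactivity descriptors such as "antifungal")
are matched per token against an assay dictionary.
"""

from __future__ import annotations

import enum
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    AnnotatedDocument,
    EntityAnnotation,
    EntityType,
    OrganismRank,
    TextSpan,
    Token,
    TokenTag,
)

log = logging.getLogger(__name__)


class DictionaryDomain(enum.Enum):
    ORGANISM = "ORGANISM"
    ASSAY = "ASSAY"


class DictionarySchemaError(ValueError):
    pass


class DuplicateVariantError(ValueError):
    pass


class DomainError(ValueError):
    pass


@dataclass
class Variant:
    base: str
    status: Optional[str] = None


@dataclass
class DictionaryEntry:
    canonical: str
    source_id: str
    phylum: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValueError("canonical must be non-empty")
        if self.species and not self.genus:
            raise ValueError(
                f"entry {self.canonical!r}: species given without genus"
            )

    @property
    def rank(self) -> OrganismRank:
        return OrganismRank.SPECIES if self.species else OrganismRank.GENUS_ONLY


@dataclass
class Dictionary:
    entries: list[DictionaryEntry]
    name: str = ""
    domain: DictionaryDomain = DictionaryDomain.ORGANISM

    def __post_init__(self) -> None:
        seen: set[str] = set()
        kept: list[DictionaryEntry] = []
        for entry in self.entries:
            variants = []
            for var in entry.variants:
                folded = var.base.lower()
                if folded in seen:
                    raise DuplicateVariantError(
                        f"duplicate variant {var.base!r} in dictionary {self.name!r}"
                    )
                if self.domain is DictionaryDomain.ASSAY and " " in var.base.strip():
                    log.warning(
                        "assay dictionary %r: multi-word variant %r rejected "
                        "(only one-word assays are recognized)",
                        self.name, var.base,
                    )
                    continue
                seen.add(folded)
                variants.append(var)
            entry.variants = variants
            kept.append(entry)
        self.entries = kept

    def genera(self) -> list[str]:
        out, seen = [], set()
        for entry in self.entries:
            g = (entry.genus or "").lower()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
        return out


_RANKS = ("phylum", "family", "genus", "species")


def read_dictionary_xml(
    xml_text: str,
    name: str = "",
    domain: DictionaryDomain = DictionaryDomain.ORGANISM,
) -> Dictionary:
    """Parse a ``<synonym>/<token>/<variant>`` dictionary document."""
    root = ET.fromstring(xml_text)
    if root.tag != "synonym":
        raise DictionarySchemaError(f"expected root <synonym>, got <{root.tag}>")
    entries: list[DictionaryEntry] = []
    for elem in root.findall("token"):
        canonical = elem.get("canonical")
        source_id = elem.get("id")
        if canonical is None:
            raise DictionarySchemaError("<token> missing required attribute 'canonical'")
        if source_id is None:
            raise DictionarySchemaError(
                f"<token canonical={canonical!r}> missing required attribute 'id'"
            )
        variants = [
            Variant(base=v.get("base", ""), status=v.get("status"))
            for v in elem.findall("variant")
        ]
        for var in variants:
            if not var.base:
                raise DictionarySchemaError(
                    f"<variant> under {canonical!r} missing 'base'"
                )
        entries.append(
            DictionaryEntry(
                canonical=canonical,
                source_id=source_id,
                variants=variants,
                **{rank: elem.get(rank) for rank in _RANKS},
            )
        )
    return Dictionary(entries=entries, name=name, domain=domain)


def write_dictionary_xml(dictionary: Dictionary) -> str:
    """Serialize a dictionary; inverse of :func:`read_dictionary_xml`."""
    root = ET.Element("synonym")
    for entry in dictionary.entries:
        attrs = {"canonical": entry.canonical, "id": entry.source_id}
        for rank in _RANKS:
            value = getattr(entry, rank)
            if value is not None:
                attrs[rank] = value
        token = ET.SubElement(root, "token", attrs)
        for var in entry.variants:
            vattrs = {"base": var.base}
            if var.status is not None:
                vattrs["status"] = var.status
            ET.SubElement(token, "variant", vattrs)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


class NoAbbreviationError(ValueError):
    pass


def abbreviate_scientific_name(full_name: str) -> str:
    """"Escherichia coli" -> "E. coli": genus initial + period + remainder."""
    words = full_name.split()
    if len(words) < 2:
        raise NoAbbreviationError(
            f"cannot abbreviate single-word name {full_name!r}"
        )
    return f"{words[0][0].upper()}. {' '.join(words[1:])}"


_UNSPECIFIED_MARKERS = ("sp.", "spec.", "spp.")


def tag_organisms(
    doc: AnnotatedDocument, dictionary: Dictionary
) -> list[EntityAnnotation]:
    """Three-pass organism tagging over the document's token stream.

    Matching is case-insensitive and longest-match-first; no emitted
    annotation span is a strict sub-span of another.  The abbreviation
    pass re-scans only names detected in pass 1, so "E. coli" with no
    prior full mention stays untagged.
    """
    if dictionary.domain is not DictionaryDomain.ORGANISM:
        raise DomainError("tag_organisms requires an ORGANISM dictionary")
    tokens = doc.tokens
    folded = [t.text.lower() for t in tokens]

    # variant phrase (word tuple) -> (entry, variant surface)
    phrase_index: dict[tuple[str, ...], DictionaryEntry] = {}
    for entry in dictionary.entries:
        for var in entry.variants:
            key = tuple(var.base.lower().split())
            phrase_index.setdefault(key, entry)

    annotations: list[EntityAnnotation] = []
    detected_variants: list[tuple[str, DictionaryEntry]] = []

    def scan(index: dict[tuple[str, ...], DictionaryEntry], rank_override=None,
             canonical_override=None, record_detections=False) -> None:
        if not index:
            return
        max_len = max(len(k) for k in index)
        occupied = [
            (a.span.start, a.span.end) for a in annotations
        ]
        i = 0
        while i < len(tokens):
            matched = False
            for length in range(min(max_len, len(tokens) - i), 0, -1):
                key = tuple(folded[i : i + length])
                entry = index.get(key)
                if entry is None:
                    continue
                span = TextSpan(tokens[i].span.start, tokens[i + length - 1].span.end)
                if any(s <= span.start and span.end <= e for s, e in occupied):
                    continue  # already covered by a longer/earlier match
                surface = doc.text[span.start : span.end]
                canonical = (
                    canonical_override(entry) if canonical_override else entry.canonical
                )
                annotations.append(
                    EntityAnnotation(
                        entity_type=EntityType.ORGANISM,
                        surface=surface,
                        span=span,
                        canonical=canonical,
                        source_id=entry.source_id,
                        rank=rank_override or entry.rank,
                    )
                )
                for j in range(i, i + length):
                    tokens[j].tag = TokenTag.ORGANISM_PART
                if record_detections:
                    detected_variants.append((" ".join(key), entry))
                i += length
                matched = True
                break
            if not matched:
                i += 1

    # Pass 1: full variant strings.
    scan(phrase_index, record_detections=True)

    # Pass 2: abbreviations of names detected in pass 1.
    abbrev_index: dict[tuple[str, ...], DictionaryEntry] = {}
    for variant_surface, entry in detected_variants:
        try:
            abbrev = abbreviate_scientific_name(variant_surface)
        except NoAbbreviationError:
            continue
        abbrev_index.setdefault(tuple(abbrev.lower().split()), entry)
    scan(abbrev_index)

    # Pass 3: genus + unspecified-species marker for every dictionary genus.
    genus_entry: dict[str, DictionaryEntry] = {}
    for entry in dictionary.entries:
        g = (entry.genus or "").lower()
        if not g:
            continue
        # prefer an entry that IS the genus (canonical == genus) for the id
        if entry.canonical.lower() == g or g not in genus_entry:
            genus_entry[g] = entry
    sp_index: dict[tuple[str, ...], DictionaryEntry] = {}
    for g, entry in genus_entry.items():
        for marker in _UNSPECIFIED_MARKERS:
            sp_index[(g, marker)] = entry
    scan(
        sp_index,
        rank_override=OrganismRank.GENUS_ONLY,
        canonical_override=lambda e: (e.genus or e.canonical),
    )

    # Longest-match invariant across passes: drop any annotation whose span
    # is a strict sub-span of another's (e.g. a bare genus hit inside a
    # later "Genus sp." hit).
    kept = [
        a
        for a in annotations
        if not any(
            b is not a and b.span.contains(a.span) and b.span != a.span
            for b in annotations
        )
    ]
    kept.sort(key=lambda a: (a.span.start, a.span.end))
    return kept


def tag_assays(
    doc: AnnotatedDocument, dictionary: Dictionary
) -> list[EntityAnnotation]:
    """Whole-token, case-insensitive assay matches ("antifungal", not
    "antifungally")."""
    if dictionary.domain is not DictionaryDomain.ASSAY:
        raise DomainError("tag_assays requires an ASSAY dictionary")
    term_index: dict[str, DictionaryEntry] = {}
    for entry in dictionary.entries:
        for var in entry.variants:
            term_index.setdefault(var.base.lower(), entry)
    annotations: list[EntityAnnotation] = []
    for tok in doc.tokens:
        entry = term_index.get(tok.text.lower())
        if entry is None:
            continue
        tok.tag = TokenTag.ASSAY
        annotations.append(
            EntityAnnotation(
                entity_type=EntityType.ASSAY,
                surface=tok.text,
                span=tok.span,
                canonical=entry.canonical,
                source_id=entry.source_id,
            )
        )
    return annotations
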