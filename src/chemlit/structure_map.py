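"""Reference-label recognition and structure-label assignment on page space.

Figures in natural-product papers print each 2D structure drawing with a
short reference label ("(1)", "VI", "3-10'") nearby.  Given page
components — structure boxes with SMILES/Molfile payloads from an optical
structure recognizer, and OCR'd text boxes — this module (1) keeps only
OCR strings that parse as reference labels (Roman or Arabic numerals,
dash-connected digits, one optional prime, one optional pair of
parentheses), and (2) assigns structures to labels one-to-one by
minimum-weight bipartite matching on box distance, per page.

The resulting label -> structure table is what joins image-channel
structures onto text-channel compound entities.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import CompoundEntity, StructurePayload

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox:
    """Pixel box, origin top-left, x rightward, y downward, half-open."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


class ComponentKind(enum.Enum):
    STRUCTURE = "STRUCTURE"
    LABEL_CANDIDATE = "LABEL_CANDIDATE"


@dataclass
class PageComponent:
    component_id: str
    page: int
    kind: ComponentKind
    box: BoundingBox
    payload: str = ""
    mol_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.page < 1:
            raise ValueError("page numbers start at 1")
        if self.kind is ComponentKind.STRUCTURE and not (self.payload or self.mol_path):
            raise ValueError(
                f"structure component {self.component_id!r} needs a SMILES "
                "payload or a mol_path"
            )


class LabelPattern(enum.Flag):
    ARABIC = enum.auto()
    ROMAN = enum.auto()
    DASHED = enum.auto()
    PRIMED = enum.auto()
    PARENTHESIZED = enum.auto()


@dataclass(frozen=True)
class LabelParse:
    raw: str
    normalized: str  # parentheses stripped, prime preserved
    pattern: LabelPattern
    numeric_value: Optional[int] = None


NOT_A_LABEL = None

_ROMAN_RE = re.compile(r"^(C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$")
_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100}


class RomanParseError(ValueError):
    pass


def roman_to_int(roman: str) -> int:
    """Standard subtractive Roman-numeral value over I, V, X, L, C.

    Malformed numerals ("IIV", "") raise :class:`RomanParseError`.
    """
    if not roman or not _ROMAN_RE.fullmatch(roman):
        raise RomanParseError(f"malformed Roman numeral {roman!r}")
    total = 0
    for i, ch in enumerate(roman):
        value = _ROMAN_VALUES[ch]
        if i + 1 < len(roman) and value < _ROMAN_VALUES[roman[i + 1]]:
            total -= value
        else:
            total += value
    return total


_PRIMES = "'’"


def classify_label(ocr_text: str) -> Optional[LabelParse]:
    """Parse an OCR string as a structure reference label, or return None.

    Grammar: Roman numeral | Arabic digits | digits-dash-digits, followed
    by at most one prime, the whole optionally in one pair of parentheses.
    """
    text = ocr_text.strip()
    pattern = LabelPattern(0)
    if len(text) >= 2 and text[0] == "(" and text[-1] == ")":
        text = text[1:-1]
        pattern |= LabelPattern.PARENTHESIZED
    normalized = text
    if text and text[-1] in _PRIMES:
        pattern |= LabelPattern.PRIMED
        text = text[:-1]
    if not text:
        return NOT_A_LABEL
    numeric_value: Optional[int] = None
    if text.isdigit():
        pattern |= LabelPattern.ARABIC
        numeric_value = int(text)
    elif re.fullmatch(r"\d+-\d+", text):
        pattern |= LabelPattern.DASHED
    else:
        try:
            numeric_value = roman_to_int(text)
        except RomanParseError:
            return NOT_A_LABEL
        pattern |= LabelPattern.ROMAN
    return LabelParse(
        raw=ocr_text, normalized=normalized, pattern=pattern,
        numeric_value=numeric_value,
    )


def normalize_label(text: str) -> str:
    """Join-key normalization: strip one pair of parentheses, keep primes."""
    text = text.strip()
    if len(text) >= 2 and text[0] == "(" and text[-1] == ")":
        text = text[1:-1]
    return text


@dataclass
class MappingEntry:
    label_normalized: str
    structure_id: str
    smiles: str
    mol_path: Optional[str] = None
    distance: float = 0.0

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def _box_distance(a: BoundingBox, b: BoundingBox, metric: str) -> float:
    if metric == "centroid":
        (ax, ay), (bx, by) = a.centroid, b.centroid
        return float(np.hypot(ax - bx, ay - by))
    if metric == "edge":
        dx = max(a.x_min - b.x_max, b.x_min - a.x_max, 0.0)
        dy = max(a.y_min - b.y_max, b.y_min - a.y_max, 0.0)
        return float(np.hypot(dx, dy))
    raise ValueError(f"unknown distance metric {metric!r}")


def map_structures_to_labels(
    structures: list[PageComponent],
    labels: list[PageComponent],
    metric: str = "centroid",
    warnings: list[str] | None = None,
) -> list[MappingEntry]:
    """One-to-one minimum-total-distance assignment of structures to labels.

    Rectangular instances (unequal counts) match min(n, m) pairs; the
    leftover components are reported through *warnings* and the log, never
    silently dropped.  Ties are broken deterministically by sorting inputs
    on (structure_id, label payload).
    """
    if warnings is None:
        warnings = []
    if not structures:
        warnings.append("no structure components; empty mapping")
        log.warning("no structure components; empty mapping")
        return []
    if not labels:
        warnings.append("no label components; all structures unmatched")
        for s in structures:
            warnings.append(f"unmatched structure {s.component_id}")
        return []

    structures = sorted(structures, key=lambda c: c.component_id)
    labels = sorted(labels, key=lambda c: (normalize_label(c.payload), c.component_id))

    cost = np.array(
        [
            [_box_distance(s.box, l.box, metric) for l in labels]
            for s in structures
        ]
    )
    rows, cols = linear_sum_assignment(cost)
    entries = [
        MappingEntry(
            label_normalized=normalize_label(labels[c].payload),
            structure_id=structures[r].component_id,
            smiles=structures[r].payload,
            mol_path=structures[r].mol_path,
            distance=float(cost[r, c]),
        )
        for r, c in zip(rows, cols)
    ]
    matched_s = set(rows)
    matched_l = set(cols)
    for i, s in enumerate(structures):
        if i not in matched_s:
            warnings.append(f"unmatched structure {s.component_id}")
    for j, l in enumerate(labels):
        if j not in matched_l:
            warnings.append(f"unmatched label {l.payload!r} ({l.component_id})")
    for msg in warnings:
        if msg.startswith("unmatched"):
            log.info("%s", msg)
    entries.sort(key=lambda e: (e.label_normalized, e.structure_id))
    return entries


_MAPPING_HEADER = ["label", "structure_id", "smiles", "mol_path", "distance"]


def write_mapping_table(entries: list[MappingEntry], path: str | Path) -> None:
    """Write the label -> structure table as TSV, sorted by label."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MAPPING_HEADER)
        for e in sorted(entries, key=lambda e: (e.label_normalized, e.structure_id)):
            writer.writerow(
                [e.label_normalized, e.structure_id, e.smiles,
                 e.mol_path or "", f"{e.distance:.3f}"]
            )


def read_mapping_table(path: str | Path) -> list[MappingEntry]:
    entries: list[MappingEntry] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _MAPPING_HEADER:
            raise ValueError(f"unexpected mapping header {header!r} in {path}")
        for row in reader:
            label, structure_id, smiles, mol_path, distance = row
            entries.append(
                MappingEntry(
                    label_normalized=label,
                    structure_id=structure_id,
                    smiles=smiles,
                    mol_path=mol_path or None,
                    distance=float(distance),
                )
            )
    return entries


def join_entities_with_structures(
    compounds: list[CompoundEntity],
    mapping: list[MappingEntry],
    warnings: list[str] | None = None,
) -> list[CompoundEntity]:
    """Attach a structure payload to every compound whose label matches a
    mapping row (labels normalized on both sides).  A label mapping to
    several structures keeps the first and warns."""
    if warnings is None:
        warnings = []
    by_label: dict[str, MappingEntry] = {}
    for entry in mapping:
        key = normalize_label(entry.label_normalized)
        if key in by_label:
            warnings.append(
                f"label {key!r} maps to multiple structures; keeping "
                f"{by_label[key].structure_id}"
            )
            log.warning("%s", warnings[-1])
            continue
        by_label[key] = entry
    for comp in compounds:
        if comp.label is None:
            continue
        entry = by_label.get(normalize_label(comp.label))
        if entry is not None:
            comp.structure = StructurePayload(
                structure_id=entry.structure_id,
                smiles=entry.smiles,
                mol_path=entry.mol_path,
            )
    return compounds


_COMPONENT_HEADER = [
    "component_id", "page", "kind",
    "x_min", "y_min", "x_max", "y_max", "payload", "mol_path",
]


def read_components_tsv(path: str | Path) -> list[PageComponent]:
    """Read a page-component table (one row per structure box or OCR box)."""
    components: list[PageComponent] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _COMPONENT_HEADER:
            raise ValueError(f"unexpected components header {header!r} in {path}")
        for lineno, row in enumerate(reader, 2):
            try:
                cid, page, kind, x0, y0, x1, y1, payload, mol_path = row
                components.append(
                    PageComponent(
                        component_id=cid,
                        page=int(page),
                        kind=ComponentKind(kind),
                        box=BoundingBox(float(x0), float(y0), float(x1), float(y1)),
                        payload=payload,
                        mol_path=mol_path or None,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return components


def write_components_tsv(components: list[PageComponent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COMPONENT_HEADER)
        for c in components:
            writer.writerow(
                [c.component_id, c.page, c.kind.value,
                 c.box.x_min, c.box.y_min, c.box.x_max, c.box.y_max,
                 c.payload, c.mol_path or ""]
            )
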