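"""Seeded synthetic generators for documents, dictionaries, page layouts.

These emulate the inputs of a natural-product curation run — abstracts
that report compound series with reference labels, name the producing
organism in a passive isolation sentence, and mention a bioactivity
word — plus the taxonomic dictionary those organisms come from and the
page-component tables an optical structure recognizer would emit.

All generators are pure functions of (parameters, seed).  Generated
corpora are closed-world: every organism placed in text comes from the
generated dictionary, so dictionary tagging is designed to achieve
perfect precision and recall on them (the desk-scale analogue of a
corpus evaluation that would otherwise need external publications).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .dict_tagger import Dictionary, DictionaryDomain, DictionaryEntry, Variant
from .model import TextSpan
from .structure_map import BoundingBox, ComponentKind, PageComponent

log = logging.getLogger(__name__)

_SYLLABLES = (
    "ba", "ce", "do", "fu", "ga", "li", "mo", "na",
    "pe", "ra", "sa", "tu", "ve", "xo", "zu",
)
#: Endings chosen to avoid every chemical-suffix heuristic match.
_GENUS_ENDINGS = ("us", "a", "um", "ix")
_SPECIES_ENDINGS = ("ensis", "icola", "orum", "alis")
_CHEM_SUFFIX_POOL = ("olide", "mycin", "oside", "icin")

_ASSAY_TERMS = (
    "antifungal", "cytotoxic", "antibacterial", "antimalarial", "antiviral",
)


def default_assay_dictionary() -> Dictionary:
    """A small drug-activity vocabulary of one-word assay descriptors."""
    entries = [
        DictionaryEntry(
            canonical=term,
            source_id=f"assay:{i + 1}",
            variants=[Variant(base=term)],
        )
        for i, term in enumerate(_ASSAY_TERMS)
    ]
    return Dictionary(entries=entries, name="assays", domain=DictionaryDomain.ASSAY)


def _pseudo_word(rng: random.Random, n_syllables: int, ending: str) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables)) + ending


def generate_dictionary(
    n_genera: int, species_per_genus: int, seed: int
) -> Dictionary:
    """Pseudo-Latin binomial dictionary: one species entry per binomial,
    genus/family/phylum attributes populated, unique ids; deterministic
    under *seed*."""
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("counts must be >= 1")
    rng = random.Random(seed)
    genera: list[str] = []
    seen: set[str] = set()
    while len(genera) < n_genera:
        g = _pseudo_word(rng, 2, rng.choice(_GENUS_ENDINGS))
        if g not in seen:
            seen.add(g)
            genera.append(g)
    entries: list[DictionaryEntry] = []
    next_id = 1000001
    used_epithets: set[str] = set()
    for genus in genera:
        for _ in range(species_per_genus):
            while True:
                epithet = _pseudo_word(rng, 1, rng.choice(_SPECIES_ENDINGS))
                if epithet not in used_epithets and epithet not in seen:
                    used_epithets.add(epithet)
                    break
            binomial = f"{genus} {epithet}"
            variants = [Variant(base=binomial)]
            entries.append(
                DictionaryEntry(
                    canonical=binomial,
                    source_id=str(next_id),
                    phylum="ascomycota",
                    family=f"{genus}aceae",
                    genus=genus,
                    species=epithet,
                    variants=variants,
                )
            )
            next_id += 1
    return Dictionary(entries=entries, name=f"synthetic-{seed}")


@dataclass
class GoldEntity:
    surface: str
    span: TextSpan
    canonical: str = ""
    source_id: str = ""


@dataclass
class GoldDocument:
    text: str = ""
    organisms: list[GoldEntity] = field(default_factory=list)
    assays: list[GoldEntity] = field(default_factory=list)
    #: (display_name, label) per expanded compound.
    compounds: list[tuple[str, str]] = field(default_factory=list)
    #: (compound label, organism surface) pairs.
    relations: list[tuple[str, str]] = field(default_factory=list)


class _TextBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0

    def add(self, piece: str) -> TextSpan:
        span = TextSpan(self.length, self.length + len(piece))
        self.parts.append(piece)
        self.length += len(piece)
        return span

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _compound_name(rng: random.Random) -> str:
    return _pseudo_word(rng, 2, rng.choice(_CHEM_SUFFIX_POOL))


def generate_abstract(
    dictionary: Dictionary, n_compound_chunks: int, seed: int
) -> tuple[str, GoldDocument]:
    """One synthetic abstract plus its gold annotations.

    Each compound chunk gets an isolation sentence tying it to a
    dictionary organism; chunk shapes mix series+label ranges (50%),
    and/to enumerations (25%), and single compounds (25%).  Reference
    labels number consecutively across chunks.  A closing sentence
    carries one assay word.  With zero chunks the document still names
    an organism and an assay.
    """
    if not dictionary.entries:
        raise ValueError("dictionary must be non-empty")
    rng = random.Random(seed)
    builder = _TextBuilder()
    gold = GoldDocument()
    next_label = 1

    def add_organism_mention() -> GoldEntity:
        entry = rng.choice(dictionary.entries)
        surface = entry.canonical.capitalize()
        builder.add("the fungus ")
        span = builder.add(surface)
        ent = GoldEntity(surface, span, entry.canonical, entry.source_id)
        gold.organisms.append(ent)
        return ent

    for _ in range(max(0, n_compound_chunks)):
        name = _compound_name(rng)
        roll = rng.random()
        if roll < 0.5:  # series range: "Xs A-C (1-3)"
            n = rng.randint(2, 5)
            letters = [chr(ord("A") + i) for i in range(n)]
            labels = [str(next_label + i) for i in range(n)]
            chunk = (
                f"{name.capitalize()}s {letters[0]}-{letters[-1]} "
                f"({labels[0]}-{labels[-1]})"
            )
        elif roll < 0.625:  # "to" range
            n = rng.randint(2, 4)
            letters = [chr(ord("A") + i) for i in range(n)]
            labels = [str(next_label + i) for i in range(n)]
            chunk = (
                f"{name.capitalize()}s {letters[0]} to {letters[-1]} "
                f"({labels[0]}-{labels[-1]})"
            )
        elif roll < 0.75:  # "and" enumeration
            letters = ["A", "B"]
            labels = [str(next_label), str(next_label + 1)]
            chunk = (
                f"{name.capitalize()}s A ({labels[0]}) and B ({labels[1]})"
            )
        else:  # single compound
            letters = [None]
            labels = [str(next_label)]
            chunk = f"{name.capitalize()} ({labels[0]})"
        next_label += len(labels)

        builder.add(chunk)
        verb = "was" if len(labels) == 1 else "were"
        builder.add(f" {verb} isolated from ")
        organism = add_organism_mention()
        builder.add(". ")

        head = name.capitalize()
        for letter, label in zip(letters, labels):
            display = f"{head} {letter}" if letter else head
            gold.compounds.append((display, label))
            gold.relations.append((label, organism.surface))

    if not gold.organisms:
        builder.add("Metabolites of ")
        add_organism_mention()
        builder.add(" were studied. ")

    assay = rng.choice(_ASSAY_TERMS)
    builder.add("The compounds showed ")
    assay_span = builder.add(assay)
    builder.add(" activity.")
    gold.assays.append(GoldEntity(assay, assay_span, canonical=assay))

    gold.text = builder.text
    return gold.text, gold


def generate_page_layout(
    n_structures: int, jitter: float, seed: int
) -> tuple[list[PageComponent], list[tuple[str, str]]]:
    """Structures on a non-overlapping grid, each with its label below it.

    Returns the component list and the gold (structure_id, label payload)
    pairing.  With jitter below half the grid spacing the nearest-label
    assignment recovers every pair; larger jitter logs a warning and may
    scramble the geometry.
    """
    if n_structures < 1:
        raise ValueError("need at least one structure")
    spacing = 200.0
    if jitter >= spacing / 2:
        log.warning(
            "jitter %.1f px >= half grid spacing %.1f px; pair recovery "
            "is not guaranteed", jitter, spacing / 2,
        )
    rng = random.Random(seed)
    smiles_pool = ("CCO", "c1ccccc1", "CC(=O)O", "C1CCCCC1", "CCN", "COC")
    cols = max(1, int(n_structures**0.5 + 0.999))
    components: list[PageComponent] = []
    gold: list[tuple[str, str]] = []
    for i in range(n_structures):
        row, col = divmod(i, cols)
        x0 = col * spacing + 40.0
        y0 = row * spacing + 20.0
        structure = PageComponent(
            component_id=f"s{i + 1}",
            page=1,
            kind=ComponentKind.STRUCTURE,
            box=BoundingBox(x0, y0, x0 + 100.0, y0 + 80.0),
            payload=smiles_pool[i % len(smiles_pool)],
            mol_path=f"structures/s{i + 1}.mol",
        )
        dx = rng.uniform(-jitter, jitter)
        dy = rng.uniform(-jitter, jitter)
        lx = x0 + 35.0 + dx
        ly = y0 + 100.0 + dy
        label_text = f"({i + 1})"
        label = PageComponent(
            component_id=f"l{i + 1}",
            page=1,
            kind=ComponentKind.LABEL_CANDIDATE,
            box=BoundingBox(lx, ly, lx + 30.0, ly + 20.0),
            payload=label_text,
        )
        components.extend([structure, label])
        gold.append((structure.component_id, label_text))
    return components, gold
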