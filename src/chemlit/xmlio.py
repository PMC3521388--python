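"""Annotation export/import XML.

A versioned, GUI-free data layer: everything the pipeline extracted from
a document collection (compounds with series/label/structure, organisms,
assays, produces-relations, warnings) in one deterministic XML file.
Outputs carry no timestamps or machine identifiers, so re-running on the
same inputs is byte-identical.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from .model import AnnotatedDocument, EntityType

SCHEMA_VERSION = "1.0"


@dataclass
class CompoundExport:
    name: str
    series: Optional[str] = None
    label: Optional[str] = None
    smiles: Optional[str] = None
    mol_path: Optional[str] = None


@dataclass
class OrganismExport:
    canonical: str
    source_id: str = ""
    rank: Optional[str] = None
    surface: str = ""


@dataclass
class AssayExport:
    term: str
    source_id: str = ""


@dataclass
class RelationExport:
    compound_label: str
    organism_canonical: str
    verb: str


@dataclass
class DocumentExport:
    doc_id: str
    compounds: list[CompoundExport] = field(default_factory=list)
    organisms: list[OrganismExport] = field(default_factory=list)
    assays: list[AssayExport] = field(default_factory=list)
    relations: list[RelationExport] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def export_document(doc: AnnotatedDocument) -> DocumentExport:
    out = DocumentExport(doc_id=doc.doc_id)
    for comp in doc.compounds:
        out.compounds.append(
            CompoundExport(
                name=comp.base_name,
                series=comp.series,
                label=comp.label,
                smiles=comp.structure.smiles if comp.structure else None,
                mol_path=comp.structure.mol_path if comp.structure else None,
            )
        )
    for ent in doc.entities:
        if ent.entity_type is EntityType.ORGANISM:
            out.organisms.append(
                OrganismExport(
                    canonical=ent.canonical,
                    source_id=ent.source_id,
                    rank=ent.rank.value if ent.rank else None,
                    surface=ent.surface,
                )
            )
        elif ent.entity_type is EntityType.ASSAY:
            out.assays.append(AssayExport(term=ent.canonical, source_id=ent.source_id))
    for rel in doc.relations:
        out.relations.append(
            RelationExport(
                compound_label=rel.compound_ref,
                organism_canonical=rel.organism.canonical,
                verb=rel.trigger_verb,
            )
        )
    out.warnings = list(doc.warnings)
    return out


def _set_opt(elem: ET.Element, attr: str, value: Optional[str]) -> None:
    if value is not None and value != "":
        elem.set(attr, value)


def write_annotations_xml(documents: list[DocumentExport]) -> str:
    root = ET.Element("collection", {"schema": SCHEMA_VERSION})
    for doc in documents:
        delem = ET.SubElement(root, "document", {"id": doc.doc_id})
        entities = ET.SubElement(delem, "entities")
        for comp in doc.compounds:
            c = ET.SubElement(entities, "compound", {"name": comp.name})
            _set_opt(c, "series", comp.series)
            _set_opt(c, "label", comp.label)
            _set_opt(c, "smiles", comp.smiles)
            _set_opt(c, "mol_path", comp.mol_path)
        for org in doc.organisms:
            o = ET.SubElement(entities, "organism", {"canonical": org.canonical})
            _set_opt(o, "id", org.source_id)
            _set_opt(o, "rank", org.rank)
            _set_opt(o, "surface", org.surface)
        for assay in doc.assays:
            a = ET.SubElement(entities, "assay", {"term": assay.term})
            _set_opt(a, "id", assay.source_id)
        relations = ET.SubElement(delem, "relations")
        for rel in doc.relations:
            ET.SubElement(
                relations,
                "produces",
                {
                    "compound_label": rel.compound_label,
                    "organism_canonical": rel.organism_canonical,
                    "verb": rel.verb,
                },
            )
        warnings_elem = ET.SubElement(delem, "warnings")
        for warning in doc.warnings:
            w = ET.SubElement(warnings_elem, "warning")
            w.text = warning
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


class AnnotationSchemaError(ValueError):
    pass


def read_annotations_xml(xml_text: str) -> list[DocumentExport]:
    root = ET.fromstring(xml_text)
    if root.tag != "collection":
        raise AnnotationSchemaError(f"expected <collection>, got <{root.tag}>")
    documents: list[DocumentExport] = []
    for delem in root.findall("document"):
        doc_id = delem.get("id")
        if doc_id is None:
            raise AnnotationSchemaError("<document> missing 'id'")
        doc = DocumentExport(doc_id=doc_id)
        entities = delem.find("entities")
        if entities is not None:
            for c in entities.findall("compound"):
                name = c.get("name")
                if name is None:
                    raise AnnotationSchemaError("<compound> missing 'name'")
                doc.compounds.append(
                    CompoundExport(
                        name=name,
                        series=c.get("series"),
                        label=c.get("label"),
                        smiles=c.get("smiles"),
                        mol_path=c.get("mol_path"),
                    )
                )
            for o in entities.findall("organism"):
                canonical = o.get("canonical")
                if canonical is None:
                    raise AnnotationSchemaError("<organism> missing 'canonical'")
                doc.organisms.append(
                    OrganismExport(
                        canonical=canonical,
                        source_id=o.get("id", ""),
                        rank=o.get("rank"),
                        surface=o.get("surface", ""),
                    )
                )
            for a in entities.findall("assay"):
                term = a.get("term")
                if term is None:
                    raise AnnotationSchemaError("<assay> missing 'term'")
                doc.assays.append(AssayExport(term=term, source_id=a.get("id", "")))
        relations = delem.find("relations")
        if relations is not None:
            for r in relations.findall("produces"):
                doc.relations.append(
                    RelationExport(
                        compound_label=r.get("compound_label", ""),
                        organism_canonical=r.get("organism_canonical", ""),
                        verb=r.get("verb", ""),
                    )
                )
        warnings_elem = delem.find("warnings")
        if warnings_elem is not None:
            doc.warnings = [w.text or "" for w in warnings_elem.findall("warning")]
        documents.append(doc)
    return documents
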