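"""End-to-end text-channel annotation: tokenize, tag, resolve, relate."""

from __future__ import annotations

from .config import DEFAULT_CONFIG, PipelineConfig
from .coordination import resolve
from .dict_tagger import Dictionary, tag_assays, tag_organisms
from .model import AnnotatedDocument
from .relations import extract_yielded
from .tokenizer import split_sentences, tag_chemicals, tokenize


def annotate_document(
    text: str,
    doc_id: str = "doc",
    organism_dicts: list[Dictionary] | None = None,
    assay_dict: Dictionary | None = None,
    gazetteer: set[str] | frozenset[str] = frozenset(),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> AnnotatedDocument:
    """Run the full text pipeline on already-preprocessed text.

    Stage order matters: dictionary taggers run before coordination so
    organism words (which can look chemical to the suffix heuristic)
    are claimed before the compound state machine sees the stream.
    When several organism dictionaries are given, the first-loaded wins
    on overlapping matches.
    """
    doc = AnnotatedDocument(doc_id=doc_id, text=text)
    doc.tokens = tokenize(text)
    tag_chemicals(doc.tokens, gazetteer, config)

    for dictionary in organism_dicts or []:
        found = tag_organisms(doc, dictionary)
        existing = [e.span for e in doc.entities]
        for ann in found:
            if not any(
                ann.span.start < sp.end and sp.start < ann.span.end
                for sp in existing
            ):
                doc.entities.append(ann)
    if assay_dict is not None:
        doc.entities.extend(tag_assays(doc, assay_dict))
    doc.entities.sort(key=lambda e: (e.span.start, e.span.end))

    doc.compounds = resolve(doc.tokens, config, warnings=doc.warnings)

    for sentence in split_sentences(doc.tokens):
        doc.relations.extend(
            extract_yielded(sentence, doc.entities, doc.compounds, config)
        )

    doc.validate()
    return doc
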