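"""Extract compound-organism "yielded" relations from sentences.

The pattern is the passive isolation idiom of natural-product abstracts:

    <compound mention(s)> ... was/were <trigger verb> ... from ... <organism>

with trigger verbs {isolated, extracted, obtained, purified, produced}.
Coordinated compound chunks distribute over the single source organism:
"Multiplolides A (1) and B (2) were isolated from Xylaria multiplex"
yields two relations.  Only the first organism annotation after "from"
is linked, and a sentence with no organism after "from" ("Compound 1 was
extracted from compound 2") yields nothing.
"""

from __future__ import annotations

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import (
    CompoundEntity,
    EntityAnnotation,
    EntityType,
    ProducesRelation,
    TextSpan,
    Token,
)


def extract_yielded(
    sentence: list[Token],
    entities: list[EntityAnnotation],
    compounds: list[CompoundEntity],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ProducesRelation]:
    """Match the passive yielded pattern within one sentence.

    ``entities`` and ``compounds`` are document-level lists; only those
    whose spans fall inside the sentence participate.
    """
    if not sentence:
        return []
    sent_span = TextSpan(sentence[0].span.start, sentence[-1].span.end)

    trigger_idx = None
    trigger_verb = None
    for idx, tok in enumerate(sentence):
        if tok.text.lower() in config.trigger_verbs and _is_passive(
            sentence, idx, config
        ):
            trigger_idx = idx
            trigger_verb = tok.text.lower()
            break
    if trigger_idx is None:
        return []

    from_idx = None
    for idx in range(trigger_idx + 1, len(sentence)):
        if sentence[idx].text.lower() == "from":
            from_idx = idx
            break
    if from_idx is None:
        return []
    from_end = sentence[from_idx].span.end

    organism = None
    for ent in sorted(entities, key=lambda e: e.span.start):
        if (
            ent.entity_type is EntityType.ORGANISM
            and ent.span.start >= from_end
            and ent.span.end <= sent_span.end
        ):
            organism = ent
            break
    if organism is None:
        return []

    verb_start = sentence[trigger_idx].span.start
    relations: list[ProducesRelation] = []
    for comp in compounds:
        if comp.span is None:
            continue
        if comp.span.start >= sent_span.start and comp.span.end <= verb_start:
            relations.append(
                ProducesRelation(
                    compound_ref=comp.label if comp.label else comp.display_name,
                    organism=organism,
                    trigger_verb=trigger_verb,
                    sentence_span=sent_span,
                    compound=comp,
                )
            )
    return relations


def _is_passive(sentence: list[Token], verb_idx: int, config: PipelineConfig) -> bool:
    lo = max(0, verb_idx - config.passive_window)
    return any(
        sentence[i].text.lower() in ("was", "were") for i in range(lo, verb_idx)
    )
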