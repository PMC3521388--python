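"""Exact/partial precision-recall scoring of extracted term lists.

Predicted and gold terms are compared per document after case-folding
and whitespace normalization, with set semantics (repeated mentions of
the same term count once).  Alignment is greedy and one-to-one: full
string equality first (exact matches, the true positives), then pairs of
leftover terms sharing at least one word (partial matches); what remains
are false positives (unexpected predictions) and false negatives
(missed gold terms).

Under the default policy a partial match counts against recall as a miss
(precision = exact / (exact + fp), recall = exact / (exact + partial +
fn)); the alternative policy credits partial matches as true positives
on both axes.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


@dataclass
class MatchCounts:
    exact: int = 0
    partial: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.exact, self.partial, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.exact + other.exact,
            self.partial + other.partial,
            self.fp + other.fp,
            self.fn + other.fn,
        )


class PartialPolicy(enum.Enum):
    PARTIAL_AS_FN = "PARTIAL_AS_FN"
    PARTIAL_AS_TP = "PARTIAL_AS_TP"


DEFAULT_POLICY = PartialPolicy.PARTIAL_AS_FN


def _normalize_term(term: str) -> str:
    return " ".join(term.lower().split())


def classify_matches(predicted: list[str], gold: list[str]) -> MatchCounts:
    """Greedy one-to-one alignment of predicted vs gold terms.

    Terms are case-folded and whitespace-normalized, deduplicated, and
    consumed at most once each: exact string equality first, then partial
    pairs sharing at least one word.
    """
    pred = sorted({_normalize_term(t) for t in predicted if t.strip()})
    gold_set = sorted({_normalize_term(t) for t in gold if t.strip()})

    exact_terms = set(pred) & set(gold_set)
    rem_pred = [t for t in pred if t not in exact_terms]
    rem_gold = [t for t in gold_set if t not in exact_terms]

    partial = 0
    used_gold: set[int] = set()
    leftover_pred: list[str] = []
    for p in rem_pred:
        p_tokens = set(p.split())
        matched = False
        for j, g in enumerate(rem_gold):
            if j in used_gold:
                continue
            if p_tokens & set(g.split()):
                used_gold.add(j)
                partial += 1
                matched = True
                break
        if not matched:
            leftover_pred.append(p)

    return MatchCounts(
        exact=len(exact_terms),
        partial=partial,
        fp=len(leftover_pred),
        fn=len(rem_gold) - len(used_gold),
    )


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def precision_ratio(
    counts: MatchCounts, policy: PartialPolicy = DEFAULT_POLICY
) -> float:
    """Unrounded percentage precision (NaN when undefined)."""
    if policy is PartialPolicy.PARTIAL_AS_TP:
        tp = counts.exact + counts.partial
    else:
        tp = counts.exact
    denom = tp + counts.fp
    if denom == 0:
        return math.nan
    return 100.0 * tp / denom


def recall_ratio(
    counts: MatchCounts, policy: PartialPolicy = DEFAULT_POLICY
) -> float:
    """Unrounded percentage recall; partial matches join the miss
    denominator under the default policy (NaN when undefined)."""
    if policy is PartialPolicy.PARTIAL_AS_TP:
        tp = counts.exact + counts.partial
        denom = tp + counts.fn
    else:
        tp = counts.exact
        denom = tp + counts.fn + counts.partial
    if denom == 0:
        return math.nan
    return 100.0 * tp / denom


def precision(counts: MatchCounts, policy: PartialPolicy = DEFAULT_POLICY) -> float:
    """Percentage precision, half-up rounded to 2 decimals for reporting.

    Returns NaN when the denominator is zero (reported as "NA").
    """
    value = precision_ratio(counts, policy)
    return value if math.isnan(value) else _round2(value)


def recall(counts: MatchCounts, policy: PartialPolicy = DEFAULT_POLICY) -> float:
    """Percentage recall, half-up rounded to 2 decimals for reporting."""
    value = recall_ratio(counts, policy)
    return value if math.isnan(value) else _round2(value)


def _fmt(value: float) -> str:
    return "NA" if math.isnan(value) else f"{value:.2f}"


_REPORT_HEADER = [
    "entity_type", "exact", "partial", "fp", "fn",
    "precision", "recall", "precision_partial_tp", "recall_partial_tp",
]


def evaluation_report(per_type: dict[str, MatchCounts]) -> str:
    """Render a TSV report (one row per entity type) with both policies.

    Scoring uses unique terms per document (set semantics); the header
    row documents the column layout.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_REPORT_HEADER)
    for entity_type, counts in per_type.items():
        writer.writerow(
            [
                entity_type, counts.exact, counts.partial, counts.fp, counts.fn,
                _fmt(precision(counts)),
                _fmt(recall(counts)),
                _fmt(precision(counts, PartialPolicy.PARTIAL_AS_TP)),
                _fmt(recall(counts, PartialPolicy.PARTIAL_AS_TP)),
            ]
        )
    return buf.getvalue()


def read_gold_tsv(path: str | Path) -> dict[tuple[str, str], list[str]]:
    """Read a gold/predicted term list: doc_id <TAB> entity_type <TAB> term."""
    table: dict[tuple[str, str], list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            doc_id, entity_type, term = row
            table.setdefault((doc_id, entity_type.lower()), []).append(term)
    return table


def evaluate_term_files(
    pred_path: str | Path,
    gold_path: str | Path,
    entity_types: list[str] | None = None,
) -> dict[str, MatchCounts]:
    """Score predicted vs gold term files per entity type, summing
    per-document counts."""
    pred = read_gold_tsv(pred_path)
    gold = read_gold_tsv(gold_path)
    if entity_types is None:
        entity_types = sorted({etype for _, etype in (*pred, *gold)})
    totals: dict[str, MatchCounts] = {}
    for etype in entity_types:
        docs = {doc for doc, t in (*pred, *gold) if t == etype}
        total = MatchCounts()
        for doc in sorted(docs):
            total = total + classify_matches(
                pred.get((doc, etype), []), gold.get((doc, etype), [])
            )
        totals[etype] = total
    return totals
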