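"""Exact-boundary evaluation against gold standoff annotations.

A predicted mention is a true positive only when its start and end
character offsets equal those of a gold mention in the same document;
anything less exact is a false positive plus a false negative. Precision,
recall and F-score follow the standard definitions

    R = TP/(TP+FN),  P = TP/(TP+FP),  F = 2PR/(P+R)

with zero-denominator conventions (0 by convention). Gold mentions carry
one of six entity classes — IUPAC (multiword systematic names), PART
(partial chemical names), SUM (sum formulas), TRIV (trivial names), ABB
(abbreviations), FAM (chemical family names) — and recall is also reported
per class.

False negatives and false positives are categorized automatically where
the pipeline's own artifacts suffice (partial match, removed by
disambiguation, removed by stoplist, tokenization error, not in
dictionary); categories needing human judgment (annotation errors,
out-of-corpus-scope mentions, non-chemicals) are emitted as
``manual_review``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .dictionary import Dictionary, RemovalReason, TermStatus
from .filters import RemovalLogEntry
from .matcher import Annotation

__all__ = [
    "EntityClass", "GoldAnnotation", "ConfusionCounts", "EvaluationReport",
    "read_gold", "score", "compute_metrics", "per_class_recall",
    "categorize_errors", "evaluate", "round_half_up",
]


class EntityClass(str, Enum):
    IUPAC = "IUPAC"
    PART = "PART"
    SUM = "SUM"
    TRIV = "TRIV"
    ABB = "ABB"
    FAM = "FAM"


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    start: int
    end: int
    surface: str
    entity_class: EntityClass

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("gold span must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13), as used for report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Gold standoff I/O
# ---------------------------------------------------------------------------

_ANN_LINE = re.compile(r"^T\d+\t(\S+) (\d+) (\d+)\t(.*)$")


def read_gold(
    doc_dir: str | Path, ann_dir: str | Path | None = None
) -> tuple[dict[str, str], list[GoldAnnotation]]:
    """Read paired .txt documents and brat-style .ann gold annotations.

    Documents without an .ann file contribute zero gold mentions (corpora
    deliberately include abstracts containing no entities). Every
    annotation is validated: known entity class, span inside the document,
    surface equal to the document substring.
    """
    doc_dir = Path(doc_dir)
    ann_dir = Path(ann_dir) if ann_dir is not None else doc_dir
    docs: dict[str, str] = {}
    gold: list[GoldAnnotation] = []
    for txt in sorted(doc_dir.glob("*.txt")):
        doc_id = txt.stem
        text = txt.read_text(encoding="utf-8")
        docs[doc_id] = text
        ann_path = ann_dir / f"{doc_id}.ann"
        if not ann_path.exists():
            continue
        for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            m = _ANN_LINE.match(line)
            if not m:
                raise ValueError(f"{ann_path}:{lineno}: malformed standoff line: {line!r}")
            label, start, end, surface = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
            try:
                cls = EntityClass(label)
            except ValueError:
                raise ValueError(f"{ann_path}:{lineno}: unknown entity class {label!r}")
            if end > len(text):
                raise ValueError(f"{ann_path}:{lineno}: span {start}-{end} out of range")
            if text[start:end] != surface:
                raise ValueError(
                    f"{ann_path}:{lineno}: surface mismatch: standoff {surface!r} "
                    f"vs document {text[start:end]!r}"
                )
            gold.append(GoldAnnotation(doc_id, start, end, surface, cls))
    return docs, gold


def write_gold(gold: Sequence[GoldAnnotation], ann_dir: str | Path) -> None:
    ann_dir = Path(ann_dir)
    by_doc: dict[str, list[GoldAnnotation]] = {}
    for g in gold:
        by_doc.setdefault(g.doc_id, []).append(g)
    for doc_id, anns in by_doc.items():
        with (ann_dir / f"{doc_id}.ann").open("w", encoding="utf-8") as fh:
            for n, g in enumerate(sorted(anns, key=lambda g: g.span), 1):
                fh.write(f"T{n}\t{g.entity_class.value} {g.start} {g.end}\t{g.surface}\n")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _kept(predicted: Iterable[Annotation]) -> list[Annotation]:
    return [a for a in predicted if a.status == "kept"]


def _pred_spans(predicted: Iterable[Annotation]) -> set[tuple[str, int, int]]:
    return {(a.doc_id, a.start, a.end) for a in _kept(predicted)}


def _gold_spans(gold: Iterable[GoldAnnotation]) -> set[tuple[str, int, int]]:
    return {(g.doc_id, g.start, g.end) for g in gold}


def score(predicted: Sequence[Annotation], gold: Sequence[GoldAnnotation]) -> ConfusionCounts:
    """Exact start/end matching, one-to-one after collapsing duplicate
    spans. Predictions in documents absent from gold count as FP."""
    pred = _pred_spans(predicted)
    gs = _gold_spans(gold)
    tp = len(pred & gs)
    return ConfusionCounts(tp=tp, fp=len(pred - gs), fn=len(gs - pred))


def compute_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


def per_class_recall(
    predicted: Sequence[Annotation], gold: Sequence[GoldAnnotation]
) -> dict[EntityClass, float | None]:
    """Recall per entity class; classes absent from gold are None."""
    pred = _pred_spans(predicted)
    out: dict[EntityClass, float | None] = {}
    for cls in EntityClass:
        spans = {(g.doc_id, g.start, g.end) for g in gold if g.entity_class is cls}
        out[cls] = (len(spans & pred) / len(spans)) if spans else None
    return out


# ---------------------------------------------------------------------------
# Error categorization
# ---------------------------------------------------------------------------

def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def categorize_errors(
    predicted: Sequence[Annotation],
    gold: Sequence[GoldAnnotation],
    raw_dictionary: Dictionary,
    filtered_dictionary: Dictionary,
    pre_disambiguation: Sequence[Annotation],
    removal_log: Sequence[RemovalLogEntry],
) -> tuple[dict[str, int], list[tuple[GoldAnnotation, str]], list[tuple[Annotation, str]]]:
    """Label every FN and FP with the first applicable automatic category.

    FN order: partial_match -> removed_by_disambiguation ->
    removed_by_stoplist -> tokenization_error -> not_in_dictionary ->
    manual_review. FP: partial_match where an overlapping gold span exists,
    else manual_review (annotation error / out-of-scope / not-a-chemical
    need human judgment and are only flagged).

    Takes the kept predictions plus the pipeline artifacts (raw and
    filtered dictionaries, pre-disambiguation annotations, removal log) and
    derives the FN/FP sets internally.
    """
    kept = _kept(predicted)
    pred_spans = _pred_spans(predicted)
    gold_spans = _gold_spans(gold)
    pre_spans = {(a.doc_id, a.start, a.end) for a in pre_disambiguation}

    stoplisted = {e.term.casefold() for e in removal_log if e.rule is RemovalReason.STOPLIST}
    all_surfaces = {
        t.surface.casefold()
        for dd in (raw_dictionary, filtered_dictionary)
        for c in dd.concepts
        for t in c.terms
    }
    active_surfaces = {
        t.surface.casefold()
        for c in filtered_dictionary.concepts
        for t in c.terms
        if t.status is TermStatus.ACTIVE
    }

    fn_labels: list[tuple[GoldAnnotation, str]] = []
    seen_fn: set[tuple[str, int, int]] = set()
    for g in sorted(gold, key=lambda g: (g.doc_id, g.span)):
        key = (g.doc_id, g.start, g.end)
        if key in pred_spans or key in seen_fn:
            continue
        seen_fn.add(key)
        surf = g.surface.casefold()
        if any(a.doc_id == g.doc_id and _overlaps(a.span, g.span) for a in kept):
            label = "partial_match"
        elif key in pre_spans:
            label = "removed_by_disambiguation"
        elif surf in stoplisted:
            label = "removed_by_stoplist"
        elif surf in active_surfaces:
            label = "tokenization_error"
        elif surf not in all_surfaces:
            label = "not_in_dictionary"
        else:
            label = "manual_review"
        fn_labels.append((g, label))

    fp_labels: list[tuple[Annotation, str]] = []
    for a in sorted(kept, key=lambda a: (a.doc_id, a.span)):
        if (a.doc_id, a.start, a.end) in gold_spans:
            continue
        if any(g.doc_id == a.doc_id and _overlaps(g.span, a.span) for g in gold):
            fp_labels.append((a, "partial_match"))
        else:
            fp_labels.append((a, "manual_review"))

    table: dict[str, int] = {}
    for _, label in fn_labels:
        table[f"fn:{label}"] = table.get(f"fn:{label}", 0) + 1
    for _, label in fp_labels:
        table[f"fp:{label}"] = table.get(f"fp:{label}", 0) + 1
    return table, fn_labels, fp_labels


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    precision: float
    recall: float
    f_score: float
    per_class: dict[EntityClass, float | None]
    error_table: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "precision": self.precision,
                "recall": self.recall,
                "f_score": self.f_score,
                "per_class_recall": {
                    k.value: v for k, v in self.per_class.items() if v is not None
                },
                "error_table": self.error_table,
            },
            indent=2,
        )

    def format_table(self) -> str:
        """Human-readable summary with two-decimal round-half-up values."""
        lines = [
            "TP\tFP\tFN\tP\tR\tF",
            f"{self.counts.tp}\t{self.counts.fp}\t{self.counts.fn}\t"
            f"{round_half_up(self.precision):.2f}\t{round_half_up(self.recall):.2f}\t"
            f"{round_half_up(self.f_score):.2f}",
            "",
            "class\trecall",
        ]
        for cls, r in self.per_class.items():
            lines.append(f"{cls.value}\t{'-' if r is None else f'{round_half_up(r):.2f}'}")
        if self.error_table:
            lines += ["", "error category\tcount"]
            lines += [f"{k}\t{v}" for k, v in sorted(self.error_table.items())]
        return "\n".join(lines)


def evaluate(
    predicted: Sequence[Annotation],
    gold: Sequence[GoldAnnotation],
    error_table: dict[str, int] | None = None,
) -> EvaluationReport:
    counts = score(predicted, gold)
    p, r, f = compute_metrics(counts)
    return EvaluationReport(counts, p, r, f, per_class_recall(predicted, gold),
                            error_table or {})
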