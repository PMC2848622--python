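"""Largest-match concept recognition over token sequences.

Dictionary terms are translated into sequences of normalized tokens and
stored in a trie. A document is tokenized the same way and scanned left to
right: at each position the longest token sequence present in the trie is
emitted as an annotation and scanning resumes after it, yielding
non-overlapping, leftmost-longest mentions. Matching is case-insensitive
(via token normalization) and word-order sensitive.

A small set of non-informative tokens ('of', 'the', 'and', 'in') is
ignored: they are deleted from term keys and skipped during comparison,
but an annotation's character span still covers them, so spans can be
compared against exact gold boundaries on the raw text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .dictionary import Dictionary
from .tokenizer import Token, TokenizerConfig, tokenize

__all__ = [
    "DEFAULT_IGNORED_TOKENS", "TermIndex", "Annotation",
    "build_index", "find_matches", "write_standoff", "write_annotation_tsv",
]

DEFAULT_IGNORED_TOKENS = frozenset({"of", "the", "and", "in"})


@dataclass(frozen=True)
class Annotation:
    """One recognized mention: span on the raw document plus candidates."""

    doc_id: str
    start: int
    end: int
    surface: str
    matched_term: str
    concept_ids: frozenset[str]
    status: str = "kept"  # or "removed_by_disambiguation"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("annotation span must be non-empty")
        if not self.concept_ids:
            raise ValueError("annotation needs at least one concept id")
        object.__setattr__(self, "concept_ids", frozenset(self.concept_ids))

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class _Node:
    __slots__ = ("children", "payload")

    def __init__(self) -> None:
        self.children: dict[str, _Node] = {}
        self.payload: set[tuple[str, str, bool]] | None = None


@dataclass
class TermIndex:
    """Trie over normalized token sequences.

    Leaf payloads are sets of ``(concept_id, term surface, preferred)``.
    ``skipped_terms`` records active terms whose tokens all normalized away
    and that therefore cannot be matched.
    """

    root: _Node = field(default_factory=_Node)
    ignored_tokens: frozenset[str] = DEFAULT_IGNORED_TOKENS
    skipped_terms: list[tuple[str, str]] = field(default_factory=list)
    n_keys: int = 0

    def insert(self, key: Sequence[str], concept_id: str, surface: str, preferred: bool) -> None:
        node = self.root
        for tok in key:
            node = node.children.setdefault(tok, _Node())
        if node.payload is None:
            node.payload = set()
            self.n_keys += 1
        node.payload.add((concept_id, surface, preferred))

    def lookup(self, key: Sequence[str]) -> set[tuple[str, str, bool]] | None:
        node = self.root
        for tok in key:
            nxt = node.children.get(tok)
            if nxt is None:
                return None
            node = nxt
        return node.payload

    def keys(self) -> Iterable[tuple[str, ...]]:
        stack: list[tuple[_Node, tuple[str, ...]]] = [(self.root, ())]
        while stack:
            node, prefix = stack.pop()
            if node.payload is not None:
                yield prefix
            for tok, child in node.children.items():
                stack.append((child, prefix + (tok,)))


def term_key(
    surface: str,
    cfg: TokenizerConfig | None = None,
    ignored: frozenset[str] = DEFAULT_IGNORED_TOKENS,
) -> tuple[str, ...]:
    """Normalized token key of a term surface, ignored tokens removed."""
    return tuple(
        t.normalized for t in tokenize(surface, cfg) if t.normalized not in ignored
    )


def build_index(
    d: Dictionary,
    cfg: TokenizerConfig | None = None,
    ignored: frozenset[str] = DEFAULT_IGNORED_TOKENS,
) -> TermIndex:
    """Index every active term of ``d``; removed terms are absent.

    Terms whose key normalizes to the empty sequence are excluded and
    listed in ``index.skipped_terms``.
    """
    idx = TermIndex(ignored_tokens=frozenset(ignored))
    for c in d.concepts:
        for t in c.terms:
            if not t.active:
                continue
            key = term_key(t.surface, cfg, idx.ignored_tokens)
            if not key:
                idx.skipped_terms.append((c.concept_id, t.surface))
                continue
            idx.insert(key, c.concept_id, t.surface, t.preferred)
    return idx


def _pick_matched_term(payload: set[tuple[str, str, bool]]) -> str:
    # deterministic representative surface: preferred first, then shortest,
    # then lexicographic
    return sorted(payload, key=lambda p: (not p[2], len(p[1]), p[1]))[0][1]


def find_matches(
    doc: str,
    idx: TermIndex,
    cfg: TokenizerConfig | None = None,
    doc_id: str = "",
) -> list[Annotation]:
    """Leftmost-longest, non-overlapping dictionary matches in ``doc``.

    Ignored tokens cannot start a match and are skipped during trie
    descent, but a match's span runs from the first to the last *matched*
    token on the raw text.
    """
    tokens = tokenize(doc, cfg)
    positions = [
        i for i, t in enumerate(tokens) if t.normalized not in idx.ignored_tokens
    ]
    annotations: list[Annotation] = []
    p = 0
    while p < len(positions):
        i = positions[p]
        node = idx.root
        best: tuple[int, set[tuple[str, str, bool]]] | None = None  # (pos idx, payload)
        q = p
        while q < len(positions):
            nxt = node.children.get(tokens[positions[q]].normalized)
            if nxt is None:
                break
            node = nxt
            if node.payload is not None:
                best = (q, node.payload)
            q += 1
        if best is None:
            p += 1
            continue
        q_last, payload = best
        start = tokens[i].start
        end = tokens[positions[q_last]].end
        annotations.append(
            Annotation(
                doc_id=doc_id,
                start=start,
                end=end,
                surface=doc[start:end],
                matched_term=_pick_matched_term(payload),
                concept_ids=frozenset(cid for cid, _, _ in payload),
            )
        )
        p = q_last + 1
    return annotations


# ---------------------------------------------------------------------------
# Standoff / TSV output
# ---------------------------------------------------------------------------

def write_standoff(annotations: Sequence[Annotation], path: str | Path,
                   label: str = "CHEM") -> None:
    """brat-style .ann: T lines for spans, # notes carrying concept ids."""
    with Path(path).open("w", encoding="utf-8") as fh:
        n = 0
        for ann in annotations:
            if ann.status != "kept":
                continue
            n += 1
            fh.write(f"T{n}\t{label} {ann.start} {ann.end}\t{ann.surface}\n")
            fh.write(
                f"#{n}\tAnnotatorNotes T{n}\t{';'.join(sorted(ann.concept_ids))}\n"
            )


def write_annotation_tsv(annotations: Sequence[Annotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("doc_id\tstart\tend\tsurface\tmatched_term\tconcept_ids\tstatus\tevidence\n")
        for a in annotations:
            fh.write(
                f"{a.doc_id}\t{a.start}\t{a.end}\t{a.surface}\t{a.matched_term}\t"
                f"{';'.join(sorted(a.concept_ids))}\t{a.status}\t{a.evidence}\n"
            )
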