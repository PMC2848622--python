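"""Rule-based homonym disambiguation for recognized mentions.

A mention is risky when its term is a *dictionary homonym* (the surface is
attached to more than one concept) or a *potential homonym* (short —
fewer than five characters — or lacking a digit, so likely to collide with
general English or gene symbols, e.g. "As" as a synonym for arsenic). A
dictionary homonym that is the preferred term of its concept is trusted as
if unambiguous.

A risky mention is kept only with context evidence:

1. another synonym of the same concept is annotated in the same piece of
   text, or
2. a *keyword* of the concept — a token from its long-form names that
   occurs fewer than ``keyword_threshold`` times in the whole dictionary —
   occurs among the text's tokens.

"Same piece of text" defaults to the whole document (abstracts are short);
sentence scope is available by configuration. Removed mentions are flagged
``removed_by_disambiguation``, never deleted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .dictionary import Dictionary, TermOrigin
from .matcher import (
    DEFAULT_IGNORED_TOKENS, Annotation, TermIndex, build_index, term_key,
)
from .tokenizer import TokenizerConfig, tokenize

__all__ = [
    "AmbiguityClass", "DisambiguationConfig", "KeywordTable",
    "classify_ambiguity", "build_keyword_table", "disambiguate",
]


class AmbiguityClass(str, Enum):
    UNAMBIGUOUS = "unambiguous"
    DICTIONARY_HOMONYM = "dictionary_homonym"
    PREFERRED_EXCEPTION = "preferred_exception"
    POTENTIAL_HOMONYM = "potential_homonym"


@dataclass(frozen=True)
class DisambiguationConfig:
    """Thresholds and semantics switches for the homonym rules.

    ``digit_semantics`` selects how the potential-homonym criterion
    combines its two triggers: "or" (the literal rule — short OR no digit)
    or "and" (short AND no digit). ``self_evidence`` lets a mention's own
    tokens satisfy the keyword condition; without it, under "or" semantics,
    nearly every trivial name would need external context.
    """

    min_length: int = 5
    digit_semantics: str = "or"  # "or" | "and"
    self_evidence: bool = True
    scope: str = "document"  # "document" | "sentence"
    keyword_threshold: int = 1000

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.digit_semantics not in ("or", "and"):
            raise ValueError("digit_semantics must be 'or' or 'and'")
        if self.scope not in ("document", "sentence"):
            raise ValueError("scope must be 'document' or 'sentence'")


def _is_potential(surface: str, cfg: DisambiguationConfig) -> bool:
    short = len(surface) < cfg.min_length
    no_digit = not any(ch.isdigit() for ch in surface)
    return (short or no_digit) if cfg.digit_semantics == "or" else (short and no_digit)


def classify_ambiguity(
    term: str, concept_id: str, d: Dictionary, cfg: DisambiguationConfig | None = None
) -> AmbiguityClass:
    """Ambiguity class of an active dictionary term for a given concept."""
    cfg = cfg or DisambiguationConfig()
    carriers = d.term_map(active_only=True).get(term.casefold())
    if not carriers or concept_id not in carriers:
        raise KeyError(f"{term!r} is not an active term of concept {concept_id}")
    if len(carriers) >= 2:
        concept = d.get(concept_id)
        if concept.preferred_term.surface.casefold() == term.casefold():
            return AmbiguityClass.PREFERRED_EXCEPTION
        return AmbiguityClass.DICTIONARY_HOMONYM
    if _is_potential(term, cfg):
        return AmbiguityClass.POTENTIAL_HOMONYM
    return AmbiguityClass.UNAMBIGUOUS


@dataclass(frozen=True)
class KeywordTable:
    """Dictionary-wide token counts plus per-concept keyword sets."""

    counts: dict[str, int]
    threshold: int
    keywords: dict[str, frozenset[str]]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("token\tcount\n")
            for tok in sorted(self.counts):
                fh.write(f"{tok}\t{self.counts[tok]}\n")


def build_keyword_table(
    d: Dictionary,
    cfg: DisambiguationConfig | None = None,
    tok_cfg: TokenizerConfig | None = None,
    ignored: frozenset[str] = DEFAULT_IGNORED_TOKENS,
) -> KeywordTable:
    """Count every normalized token across all active term surfaces, then
    give each concept the tokens of its long-form names whose dictionary-
    wide count is below the threshold.

    Long-form names are active terms that are not short-form rewrite
    products and that have at least two tokens or at least ``min_length``
    characters. Non-informative ignored tokens never become keywords.
    """
    cfg = cfg or DisambiguationConfig()
    counts: dict[str, int] = {}
    longform_tokens: dict[str, set[str]] = {}
    for c in d.concepts:
        bucket = longform_tokens.setdefault(c.concept_id, set())
        for t in c.terms:
            if not t.active:
                continue
            toks = [tok.normalized for tok in tokenize(t.surface, tok_cfg)]
            for tok in toks:
                counts[tok] = counts.get(tok, 0) + 1
            is_longform = t.origin is not TermOrigin.SHORTFORM and (
                len(toks) >= 2 or len(t.surface) >= cfg.min_length
            )
            if is_longform:
                bucket.update(tok for tok in toks if tok not in ignored)
    keywords = {
        cid: frozenset(tok for tok in toks if counts.get(tok, 0) < cfg.keyword_threshold)
        for cid, toks in longform_tokens.items()
    }
    return KeywordTable(counts, cfg.keyword_threshold, keywords)


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


def _sentence_spans(doc: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_SPLIT.finditer(doc):
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(doc)))
    return spans


def _scope_span(cfg: DisambiguationConfig, doc: str, start: int) -> tuple[int, int]:
    if cfg.scope == "document":
        return (0, len(doc))
    for s, e in _sentence_spans(doc):
        if s <= start < e:
            return (s, e)
    return (0, len(doc))


def disambiguate(
    annotations: Sequence[Annotation],
    doc: str,
    d: Dictionary,
    kt: KeywordTable,
    cfg: DisambiguationConfig | None = None,
    tok_cfg: TokenizerConfig | None = None,
    idx: TermIndex | None = None,
) -> list[Annotation]:
    """Apply the homonym rules to one document's annotations.

    Returns the same annotations with ``status`` set (kept /
    removed_by_disambiguation) and, for kept dictionary homonyms, the
    concept ids narrowed to the evidenced concepts. Never adds annotations;
    the output is order-independent and sorted by span.
    """
    cfg = cfg or DisambiguationConfig()
    if idx is None:
        idx = build_index(d, tok_cfg)
    tokens = tokenize(doc, tok_cfg)

    out: list[Annotation] = []
    anns = sorted(annotations, key=lambda a: (a.start, a.end))
    keys = {a.span: term_key(a.surface, tok_cfg, idx.ignored_tokens) for a in anns}
    for a in anns:
        key = keys[a.span]
        payload = idx.lookup(key) or {
            (cid, a.matched_term, False) for cid in a.concept_ids
        }
        concept_ids = {cid for cid, _, _ in payload}
        scope = _scope_span(cfg, doc, a.start)
        kept: set[str] = set()
        notes: list[str] = []
        for cid in sorted(concept_ids):
            surfaces = [(s, pref) for c, s, pref in payload if c == cid]
            if len(concept_ids) >= 2:
                if any(pref for _, pref in surfaces):
                    kept.add(cid)
                    notes.append(f"{cid}:preferred")
                    continue
                risky = True
            else:
                risky = all(_is_potential(s, cfg) for s, _ in surfaces)
            if not risky:
                kept.add(cid)
                continue
            ev = _evidence_for(cid, a, anns, keys, tokens, kt, cfg, scope)
            if ev:
                kept.add(cid)
                notes.append(f"{cid}:{ev}")
        if kept:
            out.append(
                Annotation(a.doc_id, a.start, a.end, a.surface, a.matched_term,
                           frozenset(kept), status="kept", evidence=";".join(notes))
            )
        else:
            out.append(
                Annotation(a.doc_id, a.start, a.end, a.surface, a.matched_term,
                           a.concept_ids, status="removed_by_disambiguation",
                           evidence="no synonym or keyword in scope")
            )
    return out


def _evidence_for(cid, a, anns, keys, tokens, kt, cfg, scope) -> str | None:
    s, e = scope
    # (1) another synonym of the same concept annotated in scope
    for b in anns:
        if b.span == a.span or not (s <= b.start and b.end <= e):
            continue
        if cid in b.concept_ids and keys[b.span] != keys[a.span]:
            return f"synonym@{b.start}-{b.end}"
    # (2) a concept keyword among the scope's tokens
    kws = kt.keywords.get(cid, frozenset())
    if kws:
        for tok in tokens:
            if not (s <= tok.start and tok.end <= e):
                continue
            if not cfg.self_evidence and a.start <= tok.start and tok.end <= a.end:
                continue
            if tok.normalized in kws:
                return f"keyword({tok.normalized})"
    return None
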