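"""Rule-based term removal and rewriting for chemical lexicons.

Lexicons assembled from curation databases carry terms that are poison for
text mining: single letters ("T" as an abbreviation for tritium), dosage
forms ("chloroquine 5%"), administrative qualifiers ("unspecified phosphate
of chloroquine diphosphate", "insulin, NOS"), and comma-inverted index
forms ("acid, gamma-vinyl-gamma-aminobutyric"). Three removal rules and
three rewrite rules address these:

Removal:
  1. *single trivial* — after tokenization and stopword removal the whole
     term is one single character, an arabic integer, or a roman numeral;
  2. *feature* — the term carries a suppression feature: a dosage in
     percent/gram/microgram/milliliter, "not otherwise specified",
     "not specified"/"unspecified", "NOS" at the end after a comma, "(NOS)"
     bracketed at the end after a space, "other" at the start or end,
     "deprecated"/"unknown"/"obsolete"/"miscellaneous" anywhere, or "no "
     at the start;
  3. *stoplist* — the term is on a reviewed stoplist of general-English
     words (built from the most frequent matched terms in a corpus).

Rewriting (originals are always retained):
  1. syntactic inversion ("acid, X" -> "X acid");
  2. possessive stripping ("Ringer's lactate" -> "Ringer lactate");
  3. long/short form splitting ("Hydrogen chloride (HCL)" ->
     "Hydrogen chloride" + "HCL").

Removal flags terms (status=removed, reason logged) rather than deleting
them, so the decision log replayed on the raw dictionary reconstructs the
filtered one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Pattern, Sequence

from .dictionary import (
    Concept, Dictionary, RemovalReason, Term, TermOrigin, TermStatus,
)
from .tokenizer import TokenizerConfig, tokenize

__all__ = [
    "FilterConfig", "RemovalLogEntry", "is_single_trivial",
    "has_suppression_feature", "apply_removal_rules", "syntactic_inversion",
    "strip_possessive", "split_long_short_form", "apply_rewrite_rules",
    "frequent_term_candidates", "roman_to_int",
]

DEFAULT_STOPWORDS = frozenset({"of", "the", "and", "in"})

_DOSAGE_UNITS = (
    r"%|percent|grams?|g|micrograms?|mcg|µg|ug|milliliters?|millilitres?|ml"
)

# (feature name, pattern); order follows the rule's own listing and the
# first match is what gets logged.
DEFAULT_FEATURE_PATTERNS: tuple[tuple[str, str], ...] = (
    ("dosage", rf"\d+(?:\.\d+)?\s*(?:{_DOSAGE_UNITS})(?![a-z])"),
    ("not-otherwise-specified", r"\bnot otherwise specified\b"),
    ("not-specified", r"\bnot specified\b"),
    ("unspecified", r"\bunspecified\b"),
    ("NOS-after-comma", r",\s*NOS\s*$"),
    ("NOS-bracketed", r"\s[(\[{]NOS[)\]}]\s*$"),
    ("other-at-start", r"^other\s"),
    ("other-at-end", r"\sother$"),
    ("deprecated", r"\bdeprecated\b"),
    ("unknown", r"\bunknown\b"),
    ("obsolete", r"\bobsolete\b"),
    ("miscellaneous", r"\bmiscellaneous\b"),
    ("no-at-start", r"^no\s"),
)


@dataclass(frozen=True)
class FilterConfig:
    """Stopwords, suppression-feature patterns, roman bound and stoplist."""

    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    feature_patterns: tuple[tuple[str, str], ...] = DEFAULT_FEATURE_PATTERNS
    roman_max: int = 3999
    roman_allowlist: frozenset[str] = frozenset()
    stoplist: frozenset[str] = frozenset()
    top_n: int = 500
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        object.__setattr__(
            self, "stopwords", frozenset(w.lower() for w in self.stopwords)
        )
        object.__setattr__(
            self, "stoplist", frozenset(w.casefold() for w in self.stoplist)
        )
        object.__setattr__(
            self, "roman_allowlist", frozenset(w.upper() for w in self.roman_allowlist)
        )
        object.__setattr__(self, "feature_patterns", tuple(self.feature_patterns))

    def compiled_features(self) -> tuple[tuple[str, Pattern[str]], ...]:
        return tuple(
            (name, re.compile(pat, re.IGNORECASE)) for name, pat in self.feature_patterns
        )


@dataclass(frozen=True)
class RemovalLogEntry:
    concept_id: str
    term: str
    rule: RemovalReason
    detail: str


_ROMAN_RE = re.compile(
    r"^M{0,4}(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$", re.IGNORECASE
)
_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}


def roman_to_int(s: str) -> int | None:
    """Value of a strict subtractive-notation roman numeral, else None."""
    if not s or not _ROMAN_RE.match(s):
        return None
    total, prev = 0, 0
    for ch in reversed(s.upper()):
        v = _ROMAN_VALUES[ch]
        total += v if v >= prev else -v
        prev = max(prev, v)
    return total


def is_single_trivial(term: str, cfg: FilterConfig | None = None) -> tuple[bool, str]:
    """Removal rule 1: after tokenization and stopword removal the whole
    term is a single character, an arabic integer, or a roman numeral.

    Returns (flag, detail) where detail names what fired.
    """
    cfg = cfg or FilterConfig()
    tokens = [
        t.normalized for t in tokenize(term, cfg.tokenizer)
        if t.normalized not in cfg.stopwords
    ]
    if len(tokens) != 1:
        return False, ""
    tok = tokens[0]
    if len(tok) == 1:
        return True, "single character"
    if tok.isdigit():
        return True, "arabic number"
    if tok.upper() not in cfg.roman_allowlist:
        value = roman_to_int(tok)
        if value is not None and value <= cfg.roman_max:
            return True, f"roman numeral ({value})"
    return False, ""


def has_suppression_feature(term: str, cfg: FilterConfig | None = None) -> str | None:
    """Removal rule 2: first suppression feature matching the term (in the
    config's pattern order, case-insensitive), or None."""
    cfg = cfg or FilterConfig()
    for name, pat in cfg.compiled_features():
        if pat.search(term):
            return name
    return None


def apply_removal_rules(
    d: Dictionary, cfg: FilterConfig | None = None
) -> tuple[Dictionary, list[RemovalLogEntry]]:
    """Flag terms failing rule 1 or 2 or present in the stoplist.

    Already-removed terms are untouched (idempotent). Concepts whose terms
    are all removed stay in the dictionary; they simply become unmatchable.
    """
    cfg = cfg or FilterConfig()
    log: list[RemovalLogEntry] = []
    new_concepts: list[Concept] = []
    for c in d.concepts:
        new_terms: list[Term] = []
        for t in c.terms:
            if not t.active:
                new_terms.append(t)
                continue
            trivial, detail = is_single_trivial(t.surface, cfg)
            feature = None if trivial else has_suppression_feature(t.surface, cfg)
            if trivial:
                reason, why = RemovalReason.SINGLE_TRIVIAL, detail
            elif feature is not None:
                reason, why = RemovalReason.FEATURE, feature
            elif t.surface.casefold() in cfg.stoplist:
                reason, why = RemovalReason.STOPLIST, "stoplist"
            else:
                new_terms.append(t)
                continue
            new_terms.append(
                replace(t, status=TermStatus.REMOVED, removal_reason=reason)
            )
            log.append(RemovalLogEntry(c.concept_id, t.surface, reason, why))
        new_concepts.append(replace(c, terms=tuple(new_terms)))
    return Dictionary(tuple(new_concepts), provenance=d.provenance), log


def syntactic_inversion(term: str) -> str | None:
    """Rewrite rule 1: undo comma inversion, re-ordering the comma-separated
    segments last-to-first ("acid, gamma-vinyl-gamma-aminobutyric" ->
    "gamma-vinyl-gamma-aminobutyric acid"). Commas inside parentheses do
    not split. None if the term has no splittable ", "."""
    segments: list[str] = []
    depth = 0
    start = 0
    i = 0
    while i < len(term):
        ch = term[i]
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif ch == "," and depth == 0 and term[i + 1 : i + 2] == " ":
            segments.append(term[start:i])
            i += 2
            start = i
            continue
        i += 1
    if not segments:
        return None
    segments.append(term[start:])
    segments = [s.strip() for s in segments if s.strip()]
    if len(segments) < 2:
        return None
    return " ".join(reversed(segments))


def strip_possessive(term: str) -> str | None:
    """Rewrite rule 2: drop every "'s" at a word end ("Ringer's lactate" ->
    "Ringer lactate"). None if nothing changed."""
    out = re.sub(r"(?<=[A-Za-z])'s\b", "", term)
    return out if out != term else None


def split_long_short_form(term: str) -> tuple[str, str] | None:
    """Rewrite rule 3: split a trailing parenthesized short form
    ("Hydrogen chloride (HCL)" -> ("Hydrogen chloride", "HCL")). None if
    the term does not end in "(...)" or nothing precedes it."""
    m = re.match(r"^(.+?)\s*\(([^()]+)\)$", term)
    if not m:
        return None
    long_form, short_form = m.group(1).strip(), m.group(2).strip()
    if not long_form or not short_form:
        return None
    return long_form, short_form


def apply_rewrite_rules(d: Dictionary) -> tuple[Dictionary, int]:
    """Add rewritten synonyms for every active source term; originals stay.

    Rewrites are applied to origin=source terms only (one pass, no
    chaining), duplicates within a concept are not added, and the count of
    added terms is returned.
    """
    added = 0
    new_concepts: list[Concept] = []
    for c in d.concepts:
        surfaces = {t.surface.casefold() for t in c.terms}
        new_terms = list(c.terms)

        def _add(surface: str, origin: TermOrigin) -> None:
            nonlocal added
            key = surface.casefold()
            if key in surfaces:
                return
            surfaces.add(key)
            new_terms.append(Term(surface, origin=origin))
            added += 1

        for t in c.terms:
            if not t.active or t.origin is not TermOrigin.SOURCE:
                continue
            inv = syntactic_inversion(t.surface)
            if inv:
                _add(inv, TermOrigin.INVERSION)
            poss = strip_possessive(t.surface)
            if poss:
                _add(poss, TermOrigin.POSSESSIVE)
            split = split_long_short_form(t.surface)
            if split:
                _add(split[0], TermOrigin.LONGFORM)
                _add(split[1], TermOrigin.SHORTFORM)
        new_concepts.append(replace(c, terms=tuple(new_terms)))
    return Dictionary(tuple(new_concepts), provenance=d.provenance), added


def frequent_term_candidates(
    d: Dictionary,
    corpus: Mapping[str, str] | Iterable[tuple[str, str]],
    top_n: int | None = None,
    cfg: FilterConfig | None = None,
) -> list[tuple[str, int]]:
    """Rank dictionary terms by raw occurrence count over a corpus.

    Indexes every document with the largest-match tagger and counts
    annotation occurrences per matched term (case-folded surface). The top
    candidates are meant for human review to build the rule-3 stoplist —
    the general-English judgment itself is not automated.
    """
    from .matcher import build_index, find_matches  # local import: cycle

    cfg = cfg or FilterConfig()
    if top_n is None:
        top_n = cfg.top_n
    docs = corpus.items() if isinstance(corpus, Mapping) else corpus
    idx = build_index(d, cfg.tokenizer)
    counts: dict[str, int] = {}
    for _doc_id, text in docs:
        for ann in find_matches(text, idx, cfg.tokenizer):
            key = ann.matched_term.casefold()
            counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def write_removal_log(log: Sequence[RemovalLogEntry], path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("concept_id\tterm\trule\tdetail\n")
        for e in log:
            fh.write(f"{e.concept_id}\t{e.term}\t{e.rule.value}\t{e.detail}\n")
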