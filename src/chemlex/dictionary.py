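"""Dictionary data model, I/O, merging, overlap and formula QC.

A *concept* is one chemical entity: a preferred term, any number of
synonyms, and a set of identifiers (CAS registry numbers, InChI strings,
prefixed cross-references into source databases). A *dictionary* is a set
of concepts. Terms are never deleted by curation — they are flagged
``removed`` with a reason, so every downstream decision can be audited and
replayed.

Merging follows the rule used when assembling composite chemical lexicons:
two entries denote the same substance if they share a CAS number, a
cross-reference, or an InChI string; the relation is closed transitively.
Cross-dictionary overlap is narrower and counts concepts sharing a CAS
number and/or an InChI string only.

The name/formula consistency checks ("robot" checks) flag concepts whose
term mentions a halide, nitrogen- or sulfur-bearing anion, or a hydrate,
while the recorded molecular formula lacks the implied element or waters
of hydration.
"""

from __future__ import annotations

import csv
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "IdentifierKind", "Identifier", "TermOrigin", "TermStatus", "RemovalReason",
    "Term", "Concept", "Dictionary", "FormulaComposition", "ConsistencyFlag",
    "ConsistencyResult", "OverlapReport", "DictionaryError",
    "read_dictionary", "write_dictionary", "merge_concepts", "compute_overlap",
    "parse_formula", "name_formula_consistency", "cas_checksum_ok",
]


class DictionaryError(ValueError):
    """Malformed dictionary input or broken invariant."""


class IdentifierKind(str, Enum):
    CAS = "CAS"
    INCHI = "InChI"
    XREF = "XREF"


_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


@dataclass(frozen=True)
class Identifier:
    kind: IdentifierKind
    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise DictionaryError("identifier value must be non-empty")
        if self.kind is IdentifierKind.CAS and not _CAS_RE.match(self.value):
            raise DictionaryError(f"malformed CAS number: {self.value!r}")
        if self.kind is IdentifierKind.INCHI and not self.value.startswith("InChI="):
            raise DictionaryError(f"InChI must begin with 'InChI=': {self.value!r}")
        if self.kind is IdentifierKind.XREF and ":" not in self.value:
            raise DictionaryError(
                f"cross-reference needs a source-database prefix ('db:id'): {self.value!r}"
            )


def cas_checksum_ok(cas: str) -> bool:
    """CAS registry check digit: weighted digit sum mod 10 (opt-in QC)."""
    if not _CAS_RE.match(cas):
        return False
    digits = cas.replace("-", "")
    body, check = digits[:-1], int(digits[-1])
    total = sum(int(d) * w for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


class TermOrigin(str, Enum):
    SOURCE = "source"
    INVERSION = "inversion"
    POSSESSIVE = "possessive"
    LONGFORM = "longform"
    SHORTFORM = "shortform"


class TermStatus(str, Enum):
    ACTIVE = "active"
    REMOVED = "removed"


class RemovalReason(str, Enum):
    SINGLE_TRIVIAL = "single_trivial"
    FEATURE = "feature"
    STOPLIST = "stoplist"


@dataclass(frozen=True)
class Term:
    surface: str
    preferred: bool = False
    origin: TermOrigin = TermOrigin.SOURCE
    status: TermStatus = TermStatus.ACTIVE
    removal_reason: RemovalReason | None = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise DictionaryError("term surface must be non-empty")
        object.__setattr__(self, "origin", TermOrigin(self.origin))
        object.__setattr__(self, "status", TermStatus(self.status))
        if self.removal_reason is not None:
            object.__setattr__(self, "removal_reason", RemovalReason(self.removal_reason))
        if (self.removal_reason is not None) != (self.status is TermStatus.REMOVED):
            raise DictionaryError(
                f"term {self.surface!r}: removal_reason present iff status=removed"
            )

    @property
    def active(self) -> bool:
        return self.status is TermStatus.ACTIVE


@dataclass(frozen=True)
class Concept:
    """One chemical entity: terms, identifiers, provenance, formula."""

    concept_id: str
    terms: tuple[Term, ...]
    identifiers: frozenset[Identifier] = frozenset()
    sources: frozenset[str] = frozenset()
    formula: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "identifiers", frozenset(self.identifiers))
        object.__setattr__(self, "sources", frozenset(self.sources))
        n_pref = sum(1 for t in self.terms if t.preferred)
        if n_pref != 1:
            raise DictionaryError(
                f"concept {self.concept_id}: exactly one preferred term required, got {n_pref}"
            )
        seen: set[str] = set()
        for t in self.terms:
            key = t.surface.casefold()
            if key in seen:
                raise DictionaryError(
                    f"concept {self.concept_id}: duplicate term surface {t.surface!r}"
                )
            seen.add(key)

    @property
    def preferred_term(self) -> Term:
        return next(t for t in self.terms if t.preferred)

    def active_terms(self) -> tuple[Term, ...]:
        return tuple(t for t in self.terms if t.active)

    def identifier_values(self, kind: IdentifierKind) -> frozenset[str]:
        return frozenset(i.value for i in self.identifiers if i.kind is kind)


@dataclass(frozen=True)
class Dictionary:
    concepts: tuple[Concept, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concepts", tuple(sorted(self.concepts, key=lambda c: c.concept_id))
        )
        ids = [c.concept_id for c in self.concepts]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DictionaryError(f"duplicate concept ids: {dup}")

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    def get(self, concept_id: str) -> Concept:
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise KeyError(concept_id)

    def term_map(self, active_only: bool = True) -> dict[str, set[str]]:
        """Case-insensitive term surface -> concept ids (rebuildable view)."""
        out: dict[str, set[str]] = {}
        for c in self.concepts:
            for t in c.terms:
                if active_only and not t.active:
                    continue
                out.setdefault(t.surface.casefold(), set()).add(c.concept_id)
        return out

    def n_terms(self, active_only: bool = True) -> int:
        return sum(
            1 for c in self.concepts for t in c.terms if t.active or not active_only
        )


# ---------------------------------------------------------------------------
# TSV / SKOS I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "concept_id", "term", "preferred", "cas", "inchi", "xrefs",
    "source", "formula", "origin", "status", "removal_reason",
]
_REQUIRED = _COLUMNS[:7]


def _term_from_row(row: Mapping[str, str]) -> Term:
    return Term(
        surface=row["term"],
        preferred=row["preferred"] == "1",
        origin=TermOrigin(row.get("origin") or "source"),
        status=TermStatus(row.get("status") or "active"),
        removal_reason=(
            RemovalReason(row["removal_reason"]) if row.get("removal_reason") else None
        ),
    )


def read_dictionary(path: str | Path, format: str = "tsv") -> Dictionary:
    """Read a dictionary from TSV or minimal SKOS RDF/XML.

    TSV needs the columns ``concept_id, term, preferred(0/1), cas, inchi,
    xrefs(;-separated), source`` with optional ``formula, origin, status,
    removal_reason``. Rows sharing a concept_id aggregate into one concept.
    """
    path = Path(path)
    if format == "skos":
        return _read_skos(path)
    if format != "tsv":
        raise DictionaryError(f"unknown dictionary format: {format!r}")

    by_id: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _REQUIRED if c not in (reader.fieldnames or [])]
        if missing:
            raise DictionaryError(f"{path}: missing TSV columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            if row.get("concept_id") in (None, "") or row.get("term") in (None, ""):
                raise DictionaryError(f"{path}:{lineno}: malformed row (empty concept_id/term)")
            try:
                term = _term_from_row(row)
                idents = set()
                for v in filter(None, (row.get("cas") or "").split(";")):
                    idents.add(Identifier(IdentifierKind.CAS, v))
                for v in filter(None, (row.get("inchi") or "").split(";")):
                    idents.add(Identifier(IdentifierKind.INCHI, v))
                for v in filter(None, (row.get("xrefs") or "").split(";")):
                    idents.add(Identifier(IdentifierKind.XREF, v))
            except (DictionaryError, ValueError) as exc:
                raise DictionaryError(f"{path}:{lineno}: {exc}") from exc
            acc = by_id.setdefault(
                row["concept_id"],
                {"terms": [], "idents": set(), "sources": set(), "formula": None},
            )
            if term.preferred and any(t.preferred for t in acc["terms"]):
                raise DictionaryError(
                    f"{path}: concept {row['concept_id']}: two preferred terms"
                )
            acc["terms"].append(term)
            acc["idents"] |= idents
            if row.get("source"):
                acc["sources"].add(row["source"])
            if row.get("formula") and acc["formula"] is None:
                acc["formula"] = row["formula"]

    concepts = []
    for cid, acc in by_id.items():
        try:
            concepts.append(
                Concept(cid, tuple(acc["terms"]), frozenset(acc["idents"]),
                        frozenset(acc["sources"]), acc["formula"])
            )
        except DictionaryError as exc:
            raise DictionaryError(f"{path}: {exc}") from exc
    return Dictionary(tuple(concepts), provenance=str(path))


def write_dictionary(d: Dictionary, path: str | Path) -> None:
    """Write canonical TSV: concepts by id, terms by surface, identifiers
    sorted and ;-joined on every row; removal status/reason persisted."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for c in d.concepts:
            cas = ";".join(sorted(c.identifier_values(IdentifierKind.CAS)))
            inchi = ";".join(sorted(c.identifier_values(IdentifierKind.INCHI)))
            xrefs = ";".join(sorted(c.identifier_values(IdentifierKind.XREF)))
            source = ";".join(sorted(c.sources))
            for t in sorted(c.terms, key=lambda t: t.surface):
                writer.writerow([
                    c.concept_id, t.surface, "1" if t.preferred else "0",
                    cas, inchi, xrefs, source, c.formula or "",
                    t.origin.value, t.status.value,
                    t.removal_reason.value if t.removal_reason else "",
                ])


_SKOS = "http://www.w3.org/2004/02/skos/core#"
_RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"


def _read_skos(path: Path) -> Dictionary:
    """Minimal SKOS reader: skos:Concept / prefLabel / altLabel, plus
    skos:notation typed CAS or InChI. Everything else is ignored."""
    root = ET.parse(path).getroot()
    concepts = []
    for el in root.iter(f"{{{_SKOS}}}Concept"):
        cid = el.get(f"{{{_RDF}}}about") or el.get(f"{{{_RDF}}}ID")
        if not cid:
            raise DictionaryError(f"{path}: skos:Concept without rdf:about")
        terms: list[Term] = []
        idents: set[Identifier] = set()
        for lab in el.findall(f"{{{_SKOS}}}prefLabel"):
            if lab.text:
                terms.insert(0, Term(lab.text, preferred=True))
        for lab in el.findall(f"{{{_SKOS}}}altLabel"):
            if lab.text and lab.text.casefold() not in {t.surface.casefold() for t in terms}:
                terms.append(Term(lab.text))
        for notation in el.findall(f"{{{_SKOS}}}notation"):
            dtype = (notation.get(f"{{{_RDF}}}datatype") or "").rsplit("#", 1)[-1].rsplit("/", 1)[-1]
            if notation.text and dtype.lower() == "cas":
                idents.add(Identifier(IdentifierKind.CAS, notation.text))
            elif notation.text and dtype.lower() == "inchi":
                idents.add(Identifier(IdentifierKind.INCHI, notation.text))
        if terms:
            concepts.append(Concept(cid, tuple(terms), frozenset(idents)))
    return Dictionary(tuple(concepts), provenance=str(path))


# ---------------------------------------------------------------------------
# Merging and overlap
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # smaller id wins as the representative
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def merge_concepts(d: Dictionary) -> Dictionary:
    """Merge concepts sharing any identifier (same kind and value),
    transitively. The merged concept keeps the id and preferred term of the
    lexicographically smallest member; other preferred flags are demoted;
    terms, identifiers and sources are unions (case-insensitive term dedup).
    """
    uf = _UnionFind(c.concept_id for c in d.concepts)
    seen: dict[Identifier, str] = {}
    for c in d.concepts:
        for ident in c.identifiers:
            if ident in seen:
                uf.union(seen[ident], c.concept_id)
            else:
                seen[ident] = c.concept_id

    groups: dict[str, list[Concept]] = {}
    for c in d.concepts:
        groups.setdefault(uf.find(c.concept_id), []).append(c)

    merged: list[Concept] = []
    for members in groups.values():
        members.sort(key=lambda c: c.concept_id)
        if len(members) == 1:
            merged.append(members[0])
            continue
        head = members[0]
        pref_key = head.preferred_term.surface.casefold()
        terms: list[Term] = []
        surf_seen: set[str] = set()
        idents: set[Identifier] = set()
        sources: set[str] = set()
        formula = None
        for m in members:
            idents |= m.identifiers
            sources |= m.sources
            if formula is None and m.formula:
                formula = m.formula
            for t in m.terms:
                key = t.surface.casefold()
                if key in surf_seen:
                    continue
                surf_seen.add(key)
                terms.append(replace(t, preferred=(key == pref_key)))
        merged.append(
            Concept(head.concept_id, tuple(terms), frozenset(idents),
                    frozenset(sources), formula)
        )
    return Dictionary(tuple(merged), provenance=d.provenance)


@dataclass(frozen=True)
class OverlapReport:
    """Concept pairs sharing a CAS and/or InChI value across dictionaries."""

    pairs: tuple[tuple[str, str], ...]
    count: int  # d1 concepts with at least one match


def compute_overlap(d1: Dictionary, d2: Dictionary) -> OverlapReport:
    """Overlap on CAS numbers and/or InChI strings (cross-references do not
    count here; they are used for merging only)."""
    index: dict[Identifier, set[str]] = {}
    for c in d2.concepts:
        for ident in c.identifiers:
            if ident.kind in (IdentifierKind.CAS, IdentifierKind.INCHI):
                index.setdefault(ident, set()).add(c.concept_id)
    pairs: set[tuple[str, str]] = set()
    matched_d1: set[str] = set()
    for c in d1.concepts:
        for ident in c.identifiers:
            if ident.kind in (IdentifierKind.CAS, IdentifierKind.INCHI):
                for other in index.get(ident, ()):
                    pairs.add((c.concept_id, other))
                    matched_d1.add(c.concept_id)
    return OverlapReport(tuple(sorted(pairs)), len(matched_d1))


# ---------------------------------------------------------------------------
# Molecular formulas and name/formula consistency
# ---------------------------------------------------------------------------

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_HYDRATE_RE = re.compile(r"[·.]\s*(\d*)\s*H2O$")


@dataclass(frozen=True)
class FormulaComposition:
    element_counts: Mapping[str, int]
    hydrate_units: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_counts", dict(self.element_counts))
        for sym, n in self.element_counts.items():
            if sym not in _ELEMENTS:
                raise DictionaryError(f"unknown element symbol: {sym!r}")
            if n < 1:
                raise DictionaryError(f"element count must be >= 1 ({sym}: {n})")
        if self.hydrate_units < 0:
            raise DictionaryError("hydrate_units must be >= 0")

    def has_element(self, symbol: str) -> bool:
        return symbol in self.element_counts


def parse_formula(text: str) -> FormulaComposition:
    """Parse a Hill-style molecular formula with an optional hydrate suffix
    ("CuSO4·5H2O" or "CuSO4.5H2O"). Anything else is rejected loudly."""
    s = text.strip()
    if not s:
        raise DictionaryError("empty molecular formula")
    hydrate = 0
    m = _HYDRATE_RE.search(s)
    if m:
        hydrate = int(m.group(1) or "1")
        s = s[: m.start()].strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN_RE.match(s, pos)
        if not m or m.group(1) not in _ELEMENTS:
            raise DictionaryError(
                f"unparseable formula token at {s[pos:pos+3]!r} in {text!r}"
            )
        sym, num = m.group(1), int(m.group(2) or "1")
        counts[sym] = counts.get(sym, 0) + num
        pos = m.end()
    if not counts:
        raise DictionaryError(f"no elements parsed from {text!r}")
    return FormulaComposition(counts, hydrate)


# trigger word -> (required element, minimum hydrate units)
_TRIGGERS: tuple[tuple[str, str | None, int], ...] = (
    ("chloride", "Cl", 0),
    ("bromide", "Br", 0),
    ("iodide", "I", 0),
    ("fluoride", "F", 0),
    ("nitrite", "N", 0),
    ("nitrate", "N", 0),
    ("sulfate", "S", 0),
    ("sulphate", "S", 0),
    ("sulfite", "S", 0),
    ("sulphite", "S", 0),
    ("dihydrate", None, 2),
    ("hydrate", None, 1),
)


@dataclass(frozen=True)
class ConsistencyFlag:
    concept_id: str
    term: str
    trigger: str
    missing: str  # element symbol, or "hydrate"


@dataclass(frozen=True)
class ConsistencyResult:
    flags: tuple[ConsistencyFlag, ...]
    skipped: bool = False  # no formula on the concept


def name_formula_consistency(c: Concept) -> ConsistencyResult:
    """Flag terms naming a halide/nitrogen/sulfur anion or hydrate that the
    concept's formula cannot support. Concepts without a formula are skipped
    (most lexicon entries carry no structure information)."""
    if not c.formula:
        return ConsistencyResult((), skipped=True)
    comp = parse_formula(c.formula)
    flags: list[ConsistencyFlag] = []
    for t in c.terms:
        words = set(re.findall(r"[a-z]+", t.surface.lower()))
        for trigger, element, min_hydrate in _TRIGGERS:
            if trigger not in words:
                continue
            if element is not None:
                if not comp.has_element(element):
                    flags.append(ConsistencyFlag(c.concept_id, t.surface, trigger, element))
            elif comp.hydrate_units < min_hydrate:
                flags.append(ConsistencyFlag(c.concept_id, t.surface, trigger, "hydrate"))
    return ConsistencyResult(tuple(flags))


def write_flags(flags: Sequence[ConsistencyFlag], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("concept_id\tterm\ttrigger\tmissing_element\n")
        for f in flags:
            fh.write(f"{f.concept_id}\t{f.term}\t{f.trigger}\t{f.missing}\n")
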