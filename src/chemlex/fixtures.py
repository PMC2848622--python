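"""Seeded synthetic dictionaries and annotated corpora.

Real chemical lexicons are licensed and the annotated corpus is an external
download, so every pipeline stage is exercised on generated fixtures with
*planted*, manifest-declared structure instead: the generator is the test
oracle. Names are synthetic (pronounceable stems plus locants), not real
chemistry, which keeps every planted property exact.

What can be planted, each at a configurable rate:

* rewritable synonyms — comma-inverted ("acid, Xic"), possessive
  ("Xer's solution") and trailing-abbreviation ("name (ABC)") forms;
* suppression-feature synonyms ("unspecified Xate mixture") whose corpus
  mentions are false positives until rule-2 filtering removes the term;
* single-character trivial synonyms removed by rule 1;
* general-English stoplist synonyms removed by the rule-3 stoplist;
* short homonym synonyms ("Qo" for a long name, like "As" for arsenic)
  whose evidence-free corpus mentions only disambiguation can remove;
* partial-name traps: the corpus annotates a supersequence of a dictionary
  term, so the matcher can only find the embedded substring.

Gold mentions follow the six entity classes with a class mix defaulting to
the proportions of a benchmark abstract corpus (391 IUPAC / 92 PART /
49 SUM / 414 TRIV / 161 ABB / 99 FAM occurrences). Abbreviation mentions
are given context evidence, alternating between a co-mentioned long-form
gold mention and a bare keyword token in the text. With all trap rates at
zero the corpus is exactly solvable: the full pipeline reaches P = R = 1.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .dictionary import (
    Concept, Dictionary, Identifier, IdentifierKind, Term,
)
from .evaluation import EntityClass, GoldAnnotation, write_gold

__all__ = ["FixtureSpec", "Fixture", "generate_dictionary", "generate_corpus",
           "generate_fixture", "write_fixture"]

#: gold occurrence counts of the benchmark corpus the class mix emulates
CORPUS_CLASS_COUNTS: dict[EntityClass, int] = {
    EntityClass.IUPAC: 391,
    EntityClass.PART: 92,
    EntityClass.SUM: 49,
    EntityClass.TRIV: 414,
    EntityClass.ABB: 161,
    EntityClass.FAM: 99,
}

_TOTAL = sum(CORPUS_CLASS_COUNTS.values())
DEFAULT_CLASS_MIX: dict[EntityClass, float] = {
    k: v / _TOTAL for k, v in CORPUS_CLASS_COUNTS.items()
}

# letters deliberately outside roman-numeral alphabet so no generated token
# is ever a roman numeral
_CONSONANTS = "bfgjknpqrstz"
_VOWELS = "aeou"

_FILLER = (
    "we measured responses across treated groups during this study and "
    "observed that exposure altered several outcomes after repeated "
    "sampling under controlled conditions"
).split()

_STOPLIST_POOL = (
    "lead", "sound", "iron", "marked", "bright", "stable", "period", "found",
    "spring", "gross",
)

_TRIVIAL_POOL = "QZJKBGPRSTNFEUWHY"


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generators need; all randomness flows from ``seed``."""

    seed: int = 0
    n_concepts: int = 24
    class_mix: Mapping[EntityClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    homonym_trap_rate: float = 0.0
    partial_trap_rate: float = 0.0
    feature_term_rate: float = 0.0
    rewriteable_rate: float = 0.0
    trivial_trap_rate: float = 0.0
    stoplist_trap_rate: float = 0.0
    n_docs: int = 20
    mentions_per_doc: float = 3.0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mix proportions sum to {total}, not 1")
        for name in ("homonym_trap_rate", "partial_trap_rate", "feature_term_rate",
                     "rewriteable_rate", "trivial_trap_rate", "stoplist_trap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_concepts < len([p for p in self.class_mix.values() if p > 0]):
            raise ValueError("need at least one concept per represented class")


def _largest_remainder(mix: Mapping[EntityClass, float], total: int) -> dict[EntityClass, int]:
    """Integer allocation of ``total`` by proportion, remainders resolved
    largest-first (ties by class name for determinism)."""
    raw = {k: v * total for k, v in mix.items() if v > 0}
    out = {k: int(v) for k, v in raw.items()}
    short = total - sum(out.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - int(raw[k])), k.value))
    for k in order[:short]:
        out[k] += 1
    return out


class _Namer:
    """Unique pronounceable stems and short codes from one RNG."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def stem(self, syllables: int = 2) -> str:
        while True:
            s = "".join(
                self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
                for _ in range(syllables)
            )
            if s not in self.used:
                self.used.add(s)
                return s

    def code(self, length: int) -> str:
        while True:
            s = "".join(self.rng.choice(_CONSONANTS.upper()) for _ in range(length))
            if s not in self.used:
                self.used.add(s)
                return s


def _make_name(kind: EntityClass, namer: _Namer, rng: random.Random) -> tuple[str, str | None]:
    """(preferred name, abbreviation synonym or None) for a concept kind."""
    a, b = namer.stem(), namer.stem()
    if kind is EntityClass.IUPAC:
        d1, d2 = sorted(rng.sample(range(1, 7), 2))
        return f"{d1},{d2}-di{a}yl {b}-{rng.randint(1, 5)}-oate", None
    if kind is EntityClass.PART:
        return f"{a}yl {b}ane", None
    if kind is EntityClass.SUM:
        return f"C{rng.randint(3, 9)}H{rng.randint(4, 19)}O{rng.randint(2, 8)}", None
    if kind is EntityClass.TRIV:
        return f"{a}{b}ine", None
    if kind is EntityClass.ABB:
        # IUPAC-styled long name so the co-mentioned evidence mention can
        # be annotated as a systematic name
        name = f"{a}yl {rng.randint(2, 6)}-{b}amide"
        return name, namer.code(3)
    if kind is EntityClass.FAM:
        return f"{a}{b}oids", None
    raise ValueError(kind)


def _random_cas(rng: random.Random) -> str:
    return f"{rng.randint(10, 9_999_999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}"


def generate_dictionary(spec: FixtureSpec) -> tuple[Dictionary, dict]:
    """Build a synthetic dictionary with planted curation targets.

    Returns the dictionary plus a manifest recording every planted property
    (term lists per trap kind, the suggested stoplist, abbreviations) for
    downstream assertions. The manifest must be handed to
    :func:`generate_corpus`.
    """
    rng = random.Random(spec.seed)
    namer = _Namer(rng)
    counts = _largest_remainder(spec.class_mix, spec.n_concepts)
    kinds: list[EntityClass] = []
    for cls in EntityClass:
        kinds.extend([cls] * counts.get(cls, 0))
    rng.shuffle(kinds)

    manifest: dict = {
        "seed": spec.seed,
        "kinds": {},
        "abbreviations": {},
        "invertible_terms": [],
        "possessive_terms": [],
        "split_terms": [],
        "feature_terms": [],
        "trivial_terms": [],
        "stoplist_terms": [],
        "stoplist": [],
        "homonym_synonyms": {},
    }

    concepts: list[Concept] = []
    sumformulas: set[str] = set()
    for i, kind in enumerate(kinds):
        cid = f"C{i:04d}"
        name, abb = _make_name(kind, namer, rng)
        while kind is EntityClass.SUM and name in sumformulas:
            name, abb = _make_name(kind, namer, rng)
        sumformulas.add(name)
        terms = [Term(name, preferred=True)]
        if abb:
            terms.append(Term(abb))
            manifest["abbreviations"][cid] = abb
        idents = {Identifier(IdentifierKind.CAS, _random_cas(rng))}
        concepts.append(Concept(cid, tuple(terms), frozenset(idents),
                                frozenset({"fixture:" + kind.value})))
        manifest["kinds"][cid] = kind.value

    def _n(rate: float) -> int:
        return round(rate * spec.n_concepts)

    def _attach(cid_index: int, term: Term) -> str:
        c = concepts[cid_index]
        concepts[cid_index] = Concept(
            c.concept_id, c.terms + (term,), c.identifiers, c.sources, c.formula
        )
        return c.concept_id

    n = len(concepts)
    for j in range(_n(spec.rewriteable_rate)):
        i = j % n
        s = namer.stem()
        cid = _attach(i, Term(f"acid, {s}ic"))
        manifest["invertible_terms"].append([cid, f"acid, {s}ic"])
        s2 = namer.stem()
        cid = _attach(i, Term(f"{s2.capitalize()}er's solution"))
        manifest["possessive_terms"].append([cid, f"{s2.capitalize()}er's solution"])
        code = namer.code(4)
        long = concepts[i].preferred_term.surface
        cid = _attach(i, Term(f"{long} ({code})"))
        manifest["split_terms"].append([cid, f"{long} ({code})"])

    for j in range(_n(spec.feature_term_rate)):
        i = (j * 5 + 1) % n
        s = namer.stem()
        surface = f"unspecified {s}ate mixture"
        cid = _attach(i, Term(surface))
        manifest["feature_terms"].append([cid, surface])

    for j in range(min(_n(spec.trivial_trap_rate), len(_TRIVIAL_POOL))):
        i = (j * 7 + 2) % n
        cid = _attach(i, Term(_TRIVIAL_POOL[j]))
        manifest["trivial_terms"].append([cid, _TRIVIAL_POOL[j]])

    for j in range(min(_n(spec.stoplist_trap_rate), len(_STOPLIST_POOL))):
        i = (j * 3 + 4) % n
        word = _STOPLIST_POOL[j]
        cid = _attach(i, Term(word.capitalize()))
        manifest["stoplist_terms"].append([cid, word.capitalize()])
        manifest["stoplist"].append(word)

    for j in range(_n(spec.homonym_trap_rate)):
        i = (j * 11 + 3) % n
        code = (namer.stem(1) + namer.stem(1)[0]).capitalize()[:2]
        while code.casefold() in {t.surface.casefold() for c in concepts for t in c.terms}:
            code = (namer.stem(1) + namer.stem(1)[0]).capitalize()[:2]
        cid = _attach(i, Term(code))
        manifest["homonym_synonyms"][cid] = code

    d = Dictionary(tuple(concepts), provenance=f"synthetic fixture seed={spec.seed}")
    return d, manifest


class _DocBuilder:
    def __init__(self, doc_id: str, rng: random.Random):
        self.doc_id = doc_id
        self.rng = rng
        self.parts: list[str] = []
        self.length = 0
        self.gold: list[GoldAnnotation] = []
        self.planted: list[tuple[str, int, int, str]] = []  # (trap kind, start, end, surface)

    def _append(self, text: str) -> int:
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start

    def filler(self, n_words: int) -> None:
        words = [self.rng.choice(_FILLER) for _ in range(n_words)]
        self._append(" ".join(words))

    def sentence(self, *items: tuple[str, str, object]) -> None:
        """items: (role, surface, payload); role in {text, gold, trap}."""
        if self.length:
            self._append(" ")
        self.filler(self.rng.randint(2, 4))
        for role, surface, payload in items:
            self._append(" ")
            start = self._append(surface)
            if role == "gold":
                self.gold.append(
                    GoldAnnotation(self.doc_id, start, start + len(surface),
                                   surface, payload)
                )
            elif role == "trap":
                self.planted.append((payload, start, start + len(surface), surface))
            self._append(" ")
            self.filler(self.rng.randint(1, 3))
        self._append(".")

    @property
    def text(self) -> str:
        return "".join(self.parts)


def generate_corpus(
    d: Dictionary, spec: FixtureSpec, dict_manifest: dict
) -> tuple[dict[str, str], list[GoldAnnotation], dict]:
    """Emit documents, exact-span gold annotations, and a corpus manifest.

    Requires the manifest produced by :func:`generate_dictionary` for the
    same spec, which identifies the planted trap terms. Gold mentions are
    distributed over documents per the class mix; trap mentions (which are
    NOT gold) are placed in documents that carry no other term or keyword
    of the trapped concept, so their only correct fate is removal.
    """
    rng = random.Random(spec.seed + 1)
    kinds = {cid: EntityClass(v) for cid, v in dict_manifest["kinds"].items()}
    by_kind: dict[EntityClass, list[str]] = {}
    for cid in sorted(kinds):
        by_kind.setdefault(kinds[cid], []).append(cid)

    n_mentions = max(len(by_kind), round(spec.mentions_per_doc * spec.n_docs))
    budgets = _largest_remainder(spec.class_mix, n_mentions)
    budgets = {k: v for k, v in budgets.items() if k in by_kind and v > 0}

    n_partial = round(spec.partial_trap_rate * budgets.get(EntityClass.PART, 0))

    trap_events: list[tuple[str, str, str]] = []  # (trap kind, concept id, surface)
    for cid, surf in dict_manifest["feature_terms"]:
        trap_events.append(("feature", cid, surf))
    for cid, surf in dict_manifest["trivial_terms"]:
        trap_events.append(("trivial", cid, surf))
    for cid, surf in dict_manifest["stoplist_terms"]:
        trap_events.append(("stoplist", cid, surf))
    for cid, surf in dict_manifest["homonym_synonyms"].items():
        trap_events.append(("homonym", cid, surf))

    # documents: #0 entity-free; traps occupy dedicated docs at the end
    n_trap_docs = min(len(trap_events), max(1, spec.n_docs // 4)) if trap_events else 0
    mention_docs = [f"d{i:03d}" for i in range(1, max(2, spec.n_docs - n_trap_docs))]
    builders: dict[str, _DocBuilder] = {
        "d000": _DocBuilder("d000", rng)
    }
    builders["d000"].sentence()
    for doc_id in mention_docs:
        builders[doc_id] = _DocBuilder(doc_id, rng)

    surface_of = {
        cid: d.get(cid).preferred_term.surface for cid in kinds
    }

    manifest: dict = dict(dict_manifest)
    manifest.update({
        "gold_counts": {}, "partial_traps": [], "trap_mentions": [],
        "abb_evidence": [], "term_mention_counts": {},
    })

    def _count(surface: str) -> None:
        key = surface.casefold()
        manifest["term_mention_counts"][key] = (
            manifest["term_mention_counts"].get(key, 0) + 1
        )

    doc_cycle = 0
    namer = _Namer(rng)

    def _next_doc() -> _DocBuilder:
        nonlocal doc_cycle
        b = builders[mention_docs[doc_cycle % len(mention_docs)]]
        doc_cycle += 1
        return b

    events: list[tuple[EntityClass, int]] = []
    for cls in sorted(budgets, key=lambda c: c.value):
        events.extend((cls, j) for j in range(budgets[cls]))
    rng.shuffle(events)

    iupac_budget_left = budgets.get(EntityClass.IUPAC, 0)
    partial_done = 0
    abb_toggle = 0
    for cls, j in events:
        cid = by_kind[cls][j % len(by_kind[cls])]
        b = _next_doc()
        if cls is EntityClass.PART and partial_done < n_partial:
            # supersequence trap: gold covers prefix + term, dictionary
            # only holds the term
            partial_done += 1
            prefix = f"{namer.stem()}oxy"
            whole = f"{prefix} {surface_of[cid]}"
            b.sentence(("gold", whole, cls))
            g = b.gold[-1]
            manifest["partial_traps"].append(
                [b.doc_id, g.start, g.end, whole, surface_of[cid]]
            )
            _count(surface_of[cid])
            continue
        if cls is EntityClass.ABB:
            abb = dict_manifest["abbreviations"][cid]
            if iupac_budget_left > 0 and abb_toggle % 2 == 0:
                # evidence by co-mention: the long form is itself gold
                iupac_budget_left -= 1
                b.sentence(("gold", surface_of[cid], EntityClass.IUPAC),
                           ("gold", abb, cls))
                _count(surface_of[cid])
                manifest["abb_evidence"].append([b.doc_id, abb, "synonym"])
            else:
                # evidence by keyword: a bare long-form token in the text
                kw = surface_of[cid].split()[0]
                b.sentence(("text", kw, None), ("gold", abb, cls))
                manifest["abb_evidence"].append([b.doc_id, abb, "keyword"])
            abb_toggle += 1
            _count(abb)
            continue
        if cls is EntityClass.IUPAC:
            if iupac_budget_left <= 0:
                continue
            iupac_budget_left -= 1
        b.sentence(("gold", surface_of[cid], cls))
        _count(surface_of[cid])

    # trap mentions, one per planted trap term, in dedicated documents
    trap_docs: list[_DocBuilder] = []
    for t, (trap_kind, cid, surf) in enumerate(trap_events):
        doc_id = f"t{t:03d}"
        b = _DocBuilder(doc_id, rng)
        b.sentence(("trap", surf, trap_kind))
        _count(surf)
        trap_docs.append(b)
        for kind2, start, end, s in b.planted:
            manifest["trap_mentions"].append([kind2, doc_id, start, end, s, cid])
        builders[doc_id] = b

    docs = {doc_id: b.text for doc_id, b in builders.items()}
    gold = [g for b in builders.values() for g in b.gold]
    for g in gold:
        manifest["gold_counts"][g.entity_class.value] = (
            manifest["gold_counts"].get(g.entity_class.value, 0) + 1
        )
    return docs, gold, manifest


@dataclass(frozen=True)
class Fixture:
    dictionary: Dictionary
    docs: dict[str, str]
    gold: list[GoldAnnotation]
    manifest: dict


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """One-call generator: dictionary + corpus + merged manifest."""
    d, dict_manifest = generate_dictionary(spec)
    docs, gold, manifest = generate_corpus(d, spec, dict_manifest)
    return Fixture(d, docs, gold, manifest)


def write_fixture(fx: Fixture, outdir: str | Path) -> None:
    """Write dictionary TSV, .txt/.ann corpus, and the JSON manifest."""
    from .dictionary import write_dictionary

    outdir = Path(outdir)
    (outdir / "corpus").mkdir(parents=True, exist_ok=True)
    write_dictionary(fx.dictionary, outdir / "dictionary.tsv")
    for doc_id, text in fx.docs.items():
        (outdir / "corpus" / f"{doc_id}.txt").write_text(text, encoding="utf-8")
    write_gold(fx.gold, outdir / "corpus")
    (outdir / "manifest.json").write_text(
        json.dumps(fx.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
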