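import itertools
import random

import pytest

from chemlex import (
    Concept, Dictionary, DictionaryError, Identifier, IdentifierKind, Term,
    cas_checksum_ok, compute_overlap, merge_concepts, name_formula_consistency,
    parse_formula, read_dictionary, write_dictionary,
)
from conftest import make_concept, make_dictionary

# ---------------------------------------------------------------------------
# model invariants
# ---------------------------------------------------------------------------

def test_identifier_validation():
    Identifier(IdentifierKind.CAS, "50-78-2")
    Identifier(IdentifierKind.INCHI, "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3")
    Identifier(IdentifierKind.XREF, "CHEBI:15365")
    with pytest.raises(DictionaryError):
        Identifier(IdentifierKind.CAS, "50-78-22")
    with pytest.raises(DictionaryError):
        Identifier(IdentifierKind.INCHI, "1S/C2H6O")
    with pytest.raises(DictionaryError):
        Identifier(IdentifierKind.XREF, "15365")


def test_cas_checksum_is_opt_in_quality_check():
    assert cas_checksum_ok("50-78-2")  # aspirin
    assert not cas_checksum_ok("50-78-3")


def test_concept_requires_exactly_one_preferred():
    with pytest.raises(DictionaryError):
        Concept("C1", (Term("a"), Term("b")))
    with pytest.raises(DictionaryError):
        Concept("C1", (Term("a", preferred=True), Term("b", preferred=True)))


def test_concept_rejects_case_duplicate_surfaces():
    with pytest.raises(DictionaryError):
        Concept("C1", (Term("Aspirin", preferred=True), Term("aspirin")))


def test_removal_reason_iff_removed():
    with pytest.raises(DictionaryError):
        Term("x", status="removed")  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

TSV = """concept_id\tterm\tpreferred\tcas\tinchi\txrefs\tsource\tformula
C1\taspirin\t1\t50-78-2\t\t\tsrcA\t
C1\tacetylsalicylic acid\t0\t\t\t\tsrcA\t
C1\tASA\t0\t\t\tCHEBI:15365\tsrcB\t
"""


def test_read_tsv_aggregates_rows(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text(TSV, encoding="utf-8")
    d = read_dictionary(p)
    assert len(d) == 1
    c = d.get("C1")
    assert len(c.terms) == 3
    assert c.preferred_term.surface == "aspirin"
    assert Identifier(IdentifierKind.CAS, "50-78-2") in c.identifiers
    assert Identifier(IdentifierKind.XREF, "CHEBI:15365") in c.identifiers
    assert c.sources == {"srcA", "srcB"}


def test_read_tsv_errors_name_line_or_concept(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "concept_id\tterm\tpreferred\tcas\tinchi\txrefs\tsource\n"
        "C1\tx\t1\tnot-a-cas\t\t\ts\n",
        encoding="utf-8",
    )
    with pytest.raises(DictionaryError, match="bad.tsv:2"):
        read_dictionary(p)
    p2 = tmp_path / "twopref.tsv"
    p2.write_text(
        "concept_id\tterm\tpreferred\tcas\tinchi\txrefs\tsource\n"
        "C1\tx\t1\t\t\t\ts\nC1\ty\t1\t\t\t\ts\n",
        encoding="utf-8",
    )
    with pytest.raises(DictionaryError, match="C1"):
        read_dictionary(p2)


def _random_fixture_dictionary():
    rng = random.Random(7)
    concepts = []
    for i in range(5):
        surfaces = [f"name{i}", f"syn{i}a", f"syn{i}b"][: rng.randint(1, 3)]
        concepts.append(
            make_concept(
                f"C{i}", *surfaces,
                cas=f"{rng.randint(100, 99999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}",
            )
        )
    return make_dictionary(*concepts)


def test_write_read_round_trip_is_identity(tmp_path):
    d = _random_fixture_dictionary()
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_dictionary(d, p1)
    d2 = read_dictionary(p1)
    assert d2.concepts == d.concepts
    write_dictionary(d2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_write_empty_dictionary_is_header_only(tmp_path):
    p = tmp_path / "empty.tsv"
    write_dictionary(Dictionary(()), p)
    lines = p.read_text(encoding="utf-8").splitlines()
    assert len(lines) == 1 and lines[0].startswith("concept_id\tterm")


def test_removed_term_status_persists(tmp_path):
    from chemlex import FilterConfig, apply_removal_rules

    d = make_dictionary(make_concept("C1", "aspirin", "T"))
    d2, log = apply_removal_rules(d, FilterConfig())
    assert len(log) == 1
    p = tmp_path / "d.tsv"
    write_dictionary(d2, p)
    d3 = read_dictionary(p)
    (removed,) = [t for t in d3.get("C1").terms if not t.active]
    assert removed.surface == "T" and removed.removal_reason.value == "single_trivial"


# ---------------------------------------------------------------------------
# SKOS reader
# ---------------------------------------------------------------------------

SKOS_XML = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:skos="http://www.w3.org/2004/02/skos/core#">
  <skos:Concept rdf:about="C1">
    <skos:prefLabel>aspirin</skos:prefLabel>
    <skos:altLabel>acetylsalicylic acid</skos:altLabel>
    <skos:notation rdf:datatype="http://example.org/types#CAS">50-78-2</skos:notation>
    <skos:broader rdf:resource="C9"/>
  </skos:Concept>
</rdf:RDF>
"""


def test_read_skos_minimal(tmp_path):
    p = tmp_path / "d.xml"
    p.write_text(SKOS_XML, encoding="utf-8")
    d = read_dictionary(p, format="skos")
    c = d.get("C1")
    assert c.preferred_term.surface == "aspirin"
    assert {t.surface for t in c.terms} == {"aspirin", "acetylsalicylic acid"}
    assert c.identifier_values(IdentifierKind.CAS) == {"50-78-2"}


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_same_cas():
    d = make_dictionary(
        make_concept("A", "alpha", cas="50-78-2"),
        make_concept("B", "beta", cas="50-78-2"),
    )
    m = merge_concepts(d)
    assert len(m) == 1
    assert {t.surface for t in m.get("A").terms} == {"alpha", "beta"}
    assert m.get("A").preferred_term.surface == "alpha"


def test_merge_transitive_chain():
    inchi = "InChI=1S/H2O/h1H2"
    d = make_dictionary(
        make_concept("A", "alpha", cas="50-78-2"),
        make_concept("B", "beta", cas="50-78-2", inchi=inchi),
        make_concept("C", "gamma", inchi=inchi),
    )
    m = merge_concepts(d)
    assert len(m) == 1
    assert {t.surface for t in m.get("A").terms} == {"alpha", "beta", "gamma"}


def test_merge_distinct_identifiers_untouched():
    d = make_dictionary(
        make_concept("A", "alpha", cas="50-78-2"),
        make_concept("B", "beta", cas="64-17-5"),
    )
    assert len(merge_concepts(d)) == 2


def _brute_force_partition(d):
    """Transitive closure of 'shares an identifier' by repeated sweeps."""
    groups = [{c.concept_id} for c in d.concepts]
    idents = {c.concept_id: c.identifiers for c in d.concepts}
    changed = True
    while changed:
        changed = False
        for g1, g2 in itertools.combinations(list(groups), 2):
            if g1 not in groups or g2 not in groups:
                continue
            i1 = set().union(*(idents[c] for c in g1))
            i2 = set().union(*(idents[c] for c in g2))
            if i1 & i2:
                groups.remove(g1)
                groups.remove(g2)
                groups.append(g1 | g2)
                changed = True
    return {frozenset(g) for g in groups}


def _random_dictionary_with_shared_ids(seed, n_concepts):
    rng = random.Random(seed)
    cas_pool = [f"{rng.randint(100, 9999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}"
                for _ in range(max(2, n_concepts // 2))]
    inchi_pool = [f"InChI=1S/X{i}" for i in range(max(2, n_concepts // 3))]
    concepts = []
    for i in range(n_concepts):
        concepts.append(
            make_concept(
                f"C{i:02d}", f"name{i}",
                cas=rng.sample(cas_pool, k=rng.randint(0, 2)),
                inchi=rng.sample(inchi_pool, k=rng.randint(0, 1)),
            )
        )
    return make_dictionary(*concepts)


@pytest.mark.parametrize("seed", range(10))
def test_merge_equals_brute_force_closure(seed):
    d = _random_dictionary_with_shared_ids(seed, n_concepts=seed * 4 + 10)
    merged = merge_concepts(d)
    expected = _brute_force_partition(d)
    assert len(merged) == len(expected)
    for group in expected:
        head = min(group)
        surfaces = {
            t.surface.casefold() for cid in group for t in d.get(cid).terms
        }
        assert {t.surface.casefold() for t in merged.get(head).terms} == surfaces


def test_merge_is_order_invariant():
    d = _random_dictionary_with_shared_ids(3, 20)
    rng = random.Random(0)
    for _ in range(5):
        concepts = list(d.concepts)
        rng.shuffle(concepts)
        m = merge_concepts(Dictionary(tuple(concepts)))
        assert m.concepts == merge_concepts(d).concepts


def test_merge_preserves_term_surface_union():
    d = _random_dictionary_with_shared_ids(5, 30)
    before = {t.surface.casefold() for c in d.concepts for t in c.terms}
    after = {t.surface.casefold() for c in merge_concepts(d).concepts for t in c.terms}
    assert before == after


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_disjoint_and_subset():
    d1 = make_dictionary(make_concept("A", "a", cas="11-11-1"))
    d2 = make_dictionary(make_concept("B", "b", cas="22-22-2"))
    assert compute_overlap(d1, d2).count == 0
    d3 = make_dictionary(
        make_concept("X1", "x1", cas="11-11-1"),
        make_concept("X2", "x2", cas="33-33-3"),
    )
    d4 = make_dictionary(
        make_concept("Y1", "y1", cas="11-11-1"),
        make_concept("Y2", "y2", cas="33-33-3"),
        make_concept("Y3", "y3", cas="44-44-4"),
    )
    assert compute_overlap(d3, d4).count == len(d3)


def test_overlap_planted_cas_and_inchi():
    """10-concept dictionaries, 4 shared CAS + 2 shared InChI, one concept
    shares both -> 5 overlapping concepts."""
    shared_cas = [f"{i}0-11-1" for i in range(10, 14)]
    shared_inchi = ["InChI=1S/s1", "InChI=1S/s2"]
    d1c, d2c = [], []
    # concepts 0-3 share CAS; 3 also shares an InChI; 4 shares only InChI
    for i in range(10):
        cas1 = [shared_cas[i]] if i < 4 else [f"{i}1-55-{i}"]
        inchi1 = (
            [shared_inchi[0]] if i == 3 else [shared_inchi[1]] if i == 4 else []
        )
        d1c.append(make_concept(f"A{i}", f"a{i}", cas=cas1, inchi=inchi1))
        cas2 = [shared_cas[i]] if i < 4 else [f"{i}2-66-{i}"]
        inchi2 = (
            [shared_inchi[0]] if i == 3 else [shared_inchi[1]] if i == 4 else []
        )
        d2c.append(make_concept(f"B{i}", f"b{i}", cas=cas2, inchi=inchi2))
    report = compute_overlap(make_dictionary(*d1c), make_dictionary(*d2c))
    assert report.count == 5
    # symmetric in matched-pair count
    rev = compute_overlap(make_dictionary(*d2c), make_dictionary(*d1c))
    assert len(rev.pairs) == len(report.pairs)


# ---------------------------------------------------------------------------
# formulas and robot checks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "formula, counts, hydrate",
    [
        ("NaCl", {"Na": 1, "Cl": 1}, 0),
        ("C6H6", {"C": 6, "H": 6}, 0),
        ("CuSO4·5H2O", {"Cu": 1, "S": 1, "O": 4}, 5),
        ("CuSO4.5H2O", {"Cu": 1, "S": 1, "O": 4}, 5),
        ("CaCl2·H2O", {"Ca": 1, "Cl": 2}, 1),
    ],
)
def test_parse_formula(formula, counts, hydrate):
    comp = parse_formula(formula)
    assert comp.element_counts == counts
    assert comp.hydrate_units == hydrate


def test_parse_formula_rejects_junk():
    with pytest.raises(DictionaryError):
        parse_formula("Xx9")
    with pytest.raises(DictionaryError):
        parse_formula("")


def test_halide_flag_raised_and_cleared():
    bad = make_concept("C1", "X chloride", formula="C6H6")
    res = name_formula_consistency(bad)
    assert [f.missing for f in res.flags] == ["Cl"] and not res.skipped
    good = make_concept("C2", "sodium chloride", formula="NaCl")
    assert name_formula_consistency(good).flags == ()


def test_hydrate_rules():
    ok = make_concept("C1", "Y dihydrate", formula="CuSO4·5H2O")
    assert name_formula_consistency(ok).flags == ()
    bad = make_concept("C2", "Y dihydrate", formula="CuSO4·H2O")
    assert [f.missing for f in name_formula_consistency(bad).flags] == ["hydrate"]


def test_sulfate_spelling_variants_need_sulfur():
    for word in ("sulfate", "sulphate", "sulfite", "sulphite"):
        c = make_concept("C1", f"X {word}", formula="C2H4")
        assert [f.missing for f in name_formula_consistency(c).flags] == ["S"]


def test_concepts_without_formula_are_skipped():
    c = make_concept("C1", "X chloride")
    res = name_formula_consistency(c)
    assert res.skipped and res.flags == ()
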