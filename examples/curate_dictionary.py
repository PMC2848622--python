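"""Curate a small chemical lexicon: removal rules, rewrite rules, merging.

Builds a toy dictionary containing the classic text-mining hazards —
a single-letter abbreviation, an administrative qualifier synonym, a
comma-inverted index form, a possessive, and a trailing abbreviation —
then shows what each curation step does to it.
"""

from chemlex import (
    Concept, Dictionary, Identifier, IdentifierKind, Term,
    apply_removal_rules, apply_rewrite_rules, merge_concepts,
)

d = Dictionary((
    Concept("C001", (
        Term("tritium", preferred=True),
        Term("T"),                                   # removed: single character
    )),
    Concept("C002", (
        Term("chloroquine diphosphate", preferred=True),
        Term("unspecified phosphate of chloroquine diphosphate"),  # removed: feature
        Term("acid, gamma-vinyl-gamma-aminobutyric"),  # rewritten by inversion
        Term("Ringer's lactate"),                      # rewritten: possessive
        Term("Hydrogen chloride (HCL)"),               # rewritten: long/short split
    ), frozenset({Identifier(IdentifierKind.CAS, "50-63-5")})),
    Concept("C003", (
        Term("chloroquine bisphosphate", preferred=True),
    ), frozenset({Identifier(IdentifierKind.CAS, "50-63-5")})),  # same CAS as C002
))

filtered, log = apply_removal_rules(d)
print(f"removal rules flagged {len(log)} terms:")
for e in log:
    print(f"  {e.concept_id}  {e.term!r:60s} rule={e.rule.value} ({e.detail})")

rewritten, added = apply_rewrite_rules(filtered)
print(f"\nrewrite rules added {added} synonyms (originals kept):")
for t in rewritten.get("C002").terms:
    if t.origin.value != "source":
        print(f"  {t.surface!r:45s} origin={t.origin.value}")

merged = merge_concepts(rewritten)
print(f"\nmerging on shared identifiers: {len(rewritten)} concepts -> {len(merged)}")
print("  (C002 and C003 share a CAS number, so their synonym lists unite)")
print(f"  merged C002 now carries {len(merged.get('C002').terms)} terms")
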