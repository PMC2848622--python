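"""Name/formula consistency checks and cross-dictionary overlap.

Salt names imply elements: a "...chloride" needs Cl in the molecular
formula, nitrite/nitrate need N, sulfate/sulfite need S, and hydrate names
need waters of hydration. Concepts without structure information are
skipped, not flagged.
"""

from chemlex import (
    Concept, Dictionary, Identifier, IdentifierKind, Term, compute_overlap,
    name_formula_consistency, parse_formula,
)

concepts = [
    Concept("Q1", (Term("sodium chloride", preferred=True),), formula="NaCl"),
    Concept("Q2", (Term("imaginol chloride", preferred=True),), formula="C6H6"),
    Concept("Q3", (Term("copper sulfate pentahydrate", preferred=True),),
            formula="CuSO4·5H2O"),
    Concept("Q4", (Term("mystery dihydrate", preferred=True),), formula="CaCl2·H2O"),
    Concept("Q5", (Term("no structure chloride", preferred=True),)),
]
for c in concepts:
    res = name_formula_consistency(c)
    state = ("skipped (no formula)" if res.skipped
             else f"{len(res.flags)} flag(s)" if res.flags else "consistent")
    print(f"{c.concept_id} {c.preferred_term.surface!r:35s} {c.formula or '-':12s} {state}")
    for f in res.flags:
        print(f"     -> term mentions {f.trigger!r} but formula lacks {f.missing}")

comp = parse_formula("CuSO4·5H2O")
print(f"\nparsed CuSO4·5H2O: elements={comp.element_counts}, "
      f"waters of hydration={comp.hydrate_units}")

d1 = Dictionary((Concept("A1", (Term("alpha", preferred=True),),
                         frozenset({Identifier(IdentifierKind.CAS, "50-78-2")})),))
d2 = Dictionary((Concept("B1", (Term("beta", preferred=True),),
                         frozenset({Identifier(IdentifierKind.CAS, "50-78-2")})),))
print(f"\noverlap on CAS/InChI between the two toy dictionaries: "
      f"{compute_overlap(d1, d2).count} concept(s)")
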