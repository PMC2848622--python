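"""Tag text with largest-match lookup, then apply the homonym rules.

The dictionary maps both "Arsenic" and its risky two-letter synonym "As"
to one concept. In a document that mentions arsenic, context evidence keeps
the short mention; in a document where "As" is just a conjunction, the
disambiguation rules remove it.
"""

from chemlex import (
    Concept, Dictionary, Term, build_index, build_keyword_table, disambiguate,
    find_matches,
)

d = Dictionary((
    Concept("C1", (Term("Arsenic", preferred=True), Term("As"))),
    Concept("C2", (Term("1,2-dichloroethane", preferred=True),)),
))
idx = build_index(d)
kt = build_keyword_table(d)

for doc in (
    "Arsenic exposure was chronic. As levels rose afterwards.",
    "As we show, results differ after 1,2-dichloroethane exposure.",
):
    print(f"document: {doc!r}")
    anns = find_matches(doc, idx, doc_id="doc")
    out = disambiguate(anns, doc, d, kt, idx=idx)
    for a in out:
        print(f"  [{a.start:3d},{a.end:3d}) {a.surface!r:22s} -> "
              f"{sorted(a.concept_ids)} {a.status}"
              + (f" ({a.evidence})" if a.evidence else ""))
    print()

print("the short synonym survives only where another synonym or a rare")
print("long-form keyword of the same concept occurs in the same document;")
print("digit-bearing names five characters or longer need no evidence.")
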