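import pytest

from chemlex import (
    Concept, Dictionary, Identifier, IdentifierKind, Term,
)


def make_concept(cid, *surfaces, cas=(), inchi=(), xrefs=(), formula=None,
                 preferred_index=0):
    terms = tuple(
        Term(s, preferred=(i == preferred_index)) for i, s in enumerate(surfaces)
    )
    idents = set()
    for v in ([cas] if isinstance(cas, str) else cas):
        idents.add(Identifier(IdentifierKind.CAS, v))
    for v in ([inchi] if isinstance(inchi, str) else inchi):
        idents.add(Identifier(IdentifierKind.INCHI, v))
    for v in ([xrefs] if isinstance(xrefs, str) else xrefs):
        idents.add(Identifier(IdentifierKind.XREF, v))
    return Concept(cid, terms, frozenset(idents), formula=formula)


def make_dictionary(*concepts):
    return Dictionary(tuple(concepts))


@pytest.fixture
def arsenic_dictionary():
    """Concept with a long preferred name and a hazardous short synonym."""
    return make_dictionary(make_concept("C1", "Arsenic", "As", cas="7440-38-2"))
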