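# Methods

## Scope and model

`chemlex` implements the rule-based workflow for dictionary-based chemical
named-entity recognition: curate a lexicon (remove hazardous terms, add
rewritten synonym variants, merge duplicate entries), translate terms into
normalized token sequences, find leftmost-longest non-overlapping mentions
in text, apply homonym rules, and score against gold annotations with
exact character boundaries. Everything is deterministic; there is no
statistical model and no training.

## Dictionary model

A concept carries exactly one preferred term, any number of synonyms, a
set of identifiers (CAS registry numbers validated against the
`d{2,7}-d{2}-d` pattern, InChI strings required to start with `InChI=`,
and cross-references required to carry a source-database prefix), optional
source labels and an optional molecular formula. Curation never deletes a
term: removal sets `status=removed` plus one reason
(`single_trivial`/`feature`/`stoplist`), so replaying the removal log on
the raw dictionary reconstructs the curated one (tested).

**Merging.** Entries sharing a CAS number, a cross-reference, or an InChI
string denote the same substance; the relation is closed transitively
(union-find, verified against a brute-force closure oracle). No manual
check of merged entries is assumed, so the choice of the surviving
preferred term is deliberately a deterministic convention: the preferred
term of the lexicographically smallest member concept id, which also names
the merged concept. Cross-dictionary *overlap* is narrower than merging —
it counts concepts sharing CAS and/or InChI values only, since
cross-references are only comparable within one source universe.

**CAS checksums** are an opt-in QC helper (`cas_checksum_ok`); the format
check alone governs identifier validity, because CAS values function as
merge keys, not as validated registry data.

**Formulas.** `parse_formula` accepts Hill-style element–count sequences
with an optional hydrate suffix (`·nH2O` or `.nH2O`, `n` defaulting to 1)
and rejects anything else loudly. The name/formula consistency checks need
only element presence: halide words imply Cl/Br/I/F, nitrite/nitrate imply
N, sulfate/sulphate/sulfite/sulphite imply S, hydrate/dihydrate imply ≥1/≥2
waters of hydration. Concepts without a formula are skipped with a marker
rather than flagged — in practice only a small minority of lexicon entries
carry structure information. Converting names to structures, InChI
computation and stereochemistry checks are out of scope.

## Term filtering and rewriting

Rule 1 removes a term when, after tokenization and stopword removal
(stopwords default to *of, the, and, in*), exactly one token remains and it
is a single character, an arabic integer, or a roman numeral. Roman
numerals are recognized in strict subtractive notation only and
case-insensitively; because strictness still removes valid romans that are
plausible drug codes ("LIX"), a `roman_allowlist` and a `roman_max` bound
are exposed.

Rule 2 suppresses terms carrying any of the listed features. The patterns
are ordered; the first match is what gets logged, but only the boolean
outcome affects downstream results. The dosage feature is interpreted as a
number optionally followed by whitespace and then a percent/gram/
microgram/milliliter unit; a range ("5–10%") matches through its endpoint.
The position-anchored features are implemented exactly as stated: "NOS"
at the end after a comma, bracketed "(NOS)" at the end after a space,
"other" at the start (followed by a space) or end (preceded by a space),
"no" at the start followed by a space — hence "noscapine" never fires.

Rule 3 (general-English stoplist) is a human judgment; the package only
produces the review input — `frequent_term_candidates` ranks matched terms
by raw occurrence count (not document frequency) over a corpus, default
top 500 — and consumes the reviewed stoplist.

The three rewrite rules (comma inversion with segments re-ordered
last-to-first, possessive stripping of every word-final `'s`, long/short
split of a trailing parenthesized token) apply to source terms only, in
one pass, with case-insensitive duplicate guards: no chaining, so a split
product is never re-inverted — chaining would invent variants the rules do
not license. Originals are always retained; applying the rules twice adds
nothing.

## Tokenization

Tokens are maximal runs of letters, digits (Unicode categories, so Greek
letters and µ are letters) and the delimiter-exception characters
`. , + - ' ( ) [ ] { }`. Normalization applies, to a fixpoint: strip
trailing full stops and commas; delete brackets with no partner inside the
token (stack-based, local to the token); peel brackets enclosing the whole
token. Then one optional suffix from a user-supplied list is removed
(longest first, never emptying the token, with a re-strip afterwards), and
the result is lower-cased. Offsets are 0-based half-open spans into the
raw document and are never altered, because evaluation is exact-boundary.
The suffix list ships empty: its contents come from prior work and
inventing one here would be unfounded linguistics. Leading/trailing
hyphens are deliberately not stripped — only the characters the rules name
are.

The combination explains the canonical hard case: in
`([Ca(2+)]i)` the outer parentheses enclose the whole token and are
peeled, but the square brackets do not (the trailing `i` is outside them),
so a dictionary entry `Ca(2+)` cannot match — a tokenization error by
design, reproduced in the tests.

## Matching

Term keys are normalized token sequences with the ignored tokens
(*of, the, and, in*) deleted; terms whose keys normalize away entirely are
excluded and recorded. Matching is greedy leftmost-longest: at each
non-ignored token position the deepest trie hit wins, scanning resumes
after it, so mentions never overlap. Whether "largest match" may let a
later, longer match override an earlier shorter one is not specified
anywhere; greedy leftmost-longest is the standard reading in concept
recognition systems and is what the brute-force oracle (all token windows,
then leftmost-longest selection) encodes. Ignored tokens inside a mention
are skipped in key comparison but covered by the span, so spans stay
comparable with gold boundaries over raw text. Homonymous keys keep all
candidate concept ids; resolution belongs to disambiguation.

## Disambiguation

Per mention and candidate concept: a key carried by ≥2 concepts is a
dictionary homonym, trusted only where it is the concept's preferred term;
a unique term is still a *potential* homonym when shorter than
`min_length=5` characters **or** containing no digit. Risky mentions
survive on evidence: (1) a different term of the same concept annotated in
scope, or (2) a concept keyword among the scope's tokens. Keywords are
tokens of a concept's long-form names (≥2 tokens or ≥ `min_length`
characters, not short-form rewrite products) occurring fewer than
`keyword_threshold=1000` times across all active term surfaces
(per-term-occurrence counting; ignored tokens never become keywords).
Scope defaults to the whole document — the intended corpora are abstracts —
with sentence scope available.

Two semantics switches exist because the literal "or" criterion makes
nearly every trivial name a potential homonym, which contradicts the high
trivial-name recall curated dictionaries retain after disambiguation.
`self_evidence=true` (default) reconciles the two: a mention's own tokens
may satisfy the keyword condition, so a unique long name evidences itself
while a bare "As" still dies without context. `digit_semantics="and"` is
the alternative reading; neither guesses further than the configuration
documents. Kept homonyms narrow their concept ids to the evidenced
concepts (no tiebreak beyond that is defined); removals are flagged, never
deleted, and the output is independent of annotation processing order.

## Evaluation

Exact start/end equality per document, one-to-one after collapsing
duplicate spans (multiplicity at one span is not defined by exact-boundary
scoring, so duplicates collapse before counting); predictions in documents
without gold are false positives. Metrics use the standard formulas with
zero-denominator values reported as 0. Per-class recall is computed over
each class's gold subset; classes absent from gold are undefined (`None`).
Report tables round half-up to two decimals.

False negatives are labeled by the first applicable automatic rule:
`partial_match` (a kept prediction overlaps the gold span without
equality), `removed_by_disambiguation` (an exact-span match existed before
disambiguation), `removed_by_stoplist`, `tokenization_error` (the gold
surface is verbatim an active dictionary term yet produced no exact
match), `not_in_dictionary` (the surface matches no term, active or
removed), else `manual_review`. False positives are `partial_match` or
`manual_review`: the remaining categories (annotation error, out of corpus
scope, not a chemical) require human judgment and are only flagged.
`categorize_errors` takes the kept predictions and the pipeline artifacts
and derives the FN/FP sets itself, since the partial-match rule needs all
kept predictions, not just the errors.

## Synthetic fixtures

The generator emulates the structure of an annotated abstract corpus, not
its text: filler sentences from a small neutral vocabulary, gold mentions
drawn from six entity classes with the mix defaulting to the benchmark
proportions 391:92:49:414:161:99 (IUPAC:PART:SUM:TRIV:ABB:FAM), ~3
mentions per document over 20 documents by default, plus at least one
entity-free document. Names are synthetic stems built from letters outside
the roman-numeral alphabet, so no generated token is ever a roman numeral
by accident and no real nomenclature is imitated. Abbreviation mentions
alternate their planted evidence between a co-mentioned long-form gold
mention and a bare keyword token. Every planted property (trap terms and
mentions with spans, the suggested stoplist, rewritable terms) is recorded
in a manifest, which is the oracle the tests compare against.

Beyond the trap kinds of the stated design (homonym, partial-name,
feature-term, rewritable), the spec of a fixture carries
`trivial_trap_rate` and `stoplist_trap_rate`: demonstrating that precision
rises at *every* curation stage requires at least one false-positive trap
per stage, and rules 1 and 3 needed their own. Trap mentions live in
dedicated documents that contain no other term or keyword of the trapped
concept, so their only correct fate is removal.

What a green fixture run does **not** establish: performance on real
dictionaries and corpora. Real lexicons have morphology, spelling
variation, nested names and annotation noise that the generator
deliberately omits; the fixtures verify the machinery (rules fire exactly
where planted, stages remove exactly their traps), not recall against
chemistry.

## Numerical and degenerate-input choices

* Rounding for report tables: two decimals, round-half-up (decimal
  arithmetic, not banker's rounding).
* Zero denominators in P/R/F: reported as 0.
* Empty documents, empty dictionaries, concepts whose terms are all
  removed, and terms normalizing to empty keys are all legal and inert.
* Tie-breaks are lexicographic everywhere (frequency ranking, merged
  preferred term, representative matched term: preferred first, then
  shortest, then lexicographic).
* All randomness in fixtures flows from one explicit integer seed; fixed
  seed ⇒ byte-identical artifacts (tested).

## Known limitations

* No sentence splitting or chemical-boundary detection; the tokenizer is
  rule-scoped on purpose.
* No fuzzy or word-order-insensitive matching.
* The SKOS reader is minimal (prefLabel/altLabel/typed notation); other
  SKOS constructs are ignored.
* Suffix list and stoplist are inputs, not products: the human judgments
  behind them are out of scope.
* Headline benchmark figures from licensed dictionaries on the real
  annotated corpus are not reproducible here; the test suite reproduces
  the derived arithmetic and all stated behaviours instead.
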