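# chemlex

Dictionary-based chemical named-entity recognition: lexicon curation,
largest-match concept tagging, rule-based homonym disambiguation, and
exact-boundary corpus evaluation.

## The problem

Finding chemical names in biomedical text with a dictionary works only as
well as the dictionary is curated. Lexicons assembled from curation
databases are full of terms that are correct as synonyms but poison for
text mining: single letters ("T" for tritium), administrative qualifiers
("unspecified phosphate of chloroquine diphosphate"), dosage forms,
comma-inverted index entries ("acid, gamma-vinyl-gamma-aminobutyric"), and
short homonyms ("As" for arsenic, which is usually just a conjunction).
`chemlex` implements the full rule-based treatment of this problem for
researchers building or evaluating chemical taggers:

* **Dictionary model and I/O** — concepts with preferred terms, synonyms
  and identifiers (CAS registry numbers, InChI strings, prefixed
  cross-references), read/written as TSV with a minimal SKOS RDF/XML
  reader; entries sharing an identifier merge transitively; overlap between
  dictionaries is counted on shared CAS/InChI values.
* **Curation rules** — removal rule 1 (single character / arabic or roman
  number after stopword removal), rule 2 (suppression features such as
  dosages, "unspecified", trailing "NOS"), rule 3 (reviewed stoplist of
  frequent general-English terms, with a frequency-candidate generator);
  rewrite rules add the syntactic inversion, the possessive-stripped form,
  and the long/short split of parenthesized abbreviations. Removals are
  flagged and logged, never deleted.
* **Chemical-aware tokenizer** — everything that is not a letter or digit
  delimits words, *except* full stops, commas, plus signs, hyphens, single
  quotes and all bracket types; tokens are stripped of trailing
  punctuation, unmatched brackets and whole-token bracket shells
  ("(aspirin)" → "aspirin", but "[Ca(2+)]i" keeps its brackets).
* **Largest-match tagger** — terms become normalized token sequences in a
  trie; documents are scanned left to right, case-insensitively and
  word-order sensitively, emitting leftmost-longest non-overlapping
  mentions; non-informative tokens (of/the/and/in) are skipped in keys but
  covered by spans.
* **Homonym disambiguation** — a mention of a dictionary homonym (unless
  it is the preferred term) or of a *potential* homonym (shorter than five
  characters or lacking a digit) is kept only if another synonym of the
  concept, or a rare keyword from its long-form names (fewer than 1000
  occurrences dictionary-wide), appears in the same text.
* **Evaluation** — exact start/end scoring against brat-style gold
  standoff with `R = TP/(TP+FN)`, `P = TP/(TP+FP)`, `F = 2PR/(P+R)`,
  per-class recall over the six mention classes
  (IUPAC/PART/SUM/TRIV/ABB/FAM), and automatic error categorization
  (partial match, removed by disambiguation, removed by stoplist,
  tokenization error, not in dictionary).
* **Synthetic fixtures** — seeded generators for dictionaries and
  annotated corpora with planted traps for every pipeline stage, so the
  whole system is testable without licensed dictionaries or downloads.

## Worked example

`python examples/evaluate_pipeline.py` generates a 34-document synthetic
corpus with planted traps and indexes it with the same dictionary in the
four curation conditions:

```
stage         active_terms  TP  FP  FN  P     R     F
unprocessed   46            60  19  0   0.76  1.00  0.86
filtered      37            60  10  0   0.86  1.00  0.92
stoplisted    33            60  6   0   0.91  1.00  0.95
disambiguated 33            60  0   0   1.00  1.00  1.00
```

Each row scores the same corpus with exact boundaries. The unprocessed
dictionary matches every planted trap mention (19 false positives);
filtering removes the single-character and feature-bearing synonyms, the
stoplist removes the general-English synonyms, and disambiguation removes
the evidence-free short homonyms — precision rises stage by stage while
recall is untouched, the direction of change these curation steps produce
on real corpora. The other examples (`curate_dictionary.py`,
`tag_and_disambiguate.py`, `formula_qc.py`) walk through curation, the
arsenic homonym, and the name/formula consistency checks.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch: the trap-free
synthetic corpus (solved perfectly by the full pipeline), the trapped
corpus with its four-stage report and the count of homonym traps removed,
dictionary merging/overlap on two generated lexicons with shared CAS
numbers, and the name/formula consistency checks. It prints the stage
tables and writes the JSON results object to `--out`.
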