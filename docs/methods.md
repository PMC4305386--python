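# Methods

## Pipeline model

The package implements a concept-based literature retrieval pipeline for
biocuration triage. Its stages, in execution order:

1. **Corpus ingestion.** PubMed article-set XML (NLM
   `PubmedArticleSet/PubmedArticle/MedlineCitation` dialect) is parsed
   into records carrying PMID, title, abstract, MeSH descriptor names,
   publication date and journal. Only the title, abstract and MeSH
   headings are processed; full text is out of scope. Citations without
   a PMID or title are skipped with a warning — downstream curation
   displays hinge on titles, so a title-less record is unusable.
2. **Versioned store.** Records are written to an embedded sqlite3
   key-value store under the zero-padded-to-9-digits, character-reversed
   PMID. Reversal spreads sequential PMIDs uniformly across the
   keyspace (the load-balancing trick of distributed column stores,
   emulated here on one node); padding first makes the scheme injective
   below 10⁹ and keys uniform length. Every write carries a timestamp;
   the store retains the `max_versions` (default 3) largest timestamps
   per key regardless of arrival order, and reads return the
   max-timestamp payload. Nightly-style batches share one timestamp and
   report a partition of the batch into new / replaced / stale.
3. **Dictionary compilation.** OBO 1.2 ontologies (parsed with
   `obonet`) and tab-delimited gene tables become per-vocabulary
   matching dictionaries plus a reflexive-transitive is_a closure.
4. **Tagging.** Gazetteer matching over token sequences, plus regex
   mutation matching.
5. **Indexing and retrieval.** An inverted index over stemmed text
   tokens and concept annotations; conjunctive clause queries with
   disjunctive expansions, species constraint, filter chains, facet
   counts and TF-IDF ranking.
6. **Curation log.** An append-only JSON-lines event log drives
   read-by / in-database / aspect decorations on results.

## Stemming

The Snowball English ("Porter2") stemmer is implemented in
`_porter2.py` from the published algorithm: R1/R2 regions (with the
gener-/commun-/arsen- prefix exception), y/Y consonant marking, steps
0–5 and both exceptional-form lists. Both dictionary surface forms and
article text pass through the same stemmer, so retrieval correctness
depends only on the stemmer being a deterministic function applied
consistently on both sides; fidelity to the published algorithm is
additionally pinned by a frozen table of hand-verified vectors covering
every rule step (see `tests/test_stemmer.py`).

## Case classes

Each surface form is routed to one of two gazetteers:

- **sensitive** (matched verbatim): forms of ≤ 4 characters or with an
  uppercase letter after the first — the profile of gene symbols and
  abbreviations ("Retn", "FIZZ3", "NaCl") whose case-folded forms
  collide with ordinary words;
- **insensitive** (lowercased + stemmed): everything else.

The threshold of 4 is a design choice: most informative English words
are longer, most gene symbols shorter or mixed-case. One deliberate
override: the organism dictionary forces all names insensitive, because
species common names ("rat", "human") are ordinary words that must match
their plurals; the short-symbol rationale does not apply to them.

## Matching

Fields are tokenized into maximal letter/digit runs (hyphens and
slashes separate tokens) with character offsets. Per vocabulary, the
scan is leftmost-longest: at each position the longest window matching
either gazetteer wins, shorter overlapping matches within the same
vocabulary are dropped, and the scan resumes after the match. Matches
from different vocabularies may overlap freely. This is the standard
gazetteer discipline; it makes occurrence counts well defined. MeSH
headings are joined with `"; "` into one `mesh` field but tokenized
per heading, so no match window can span two headings. Lookup is a
token-tuple hash per window length — at abstract scale this is
indistinguishable from an automaton-based multi-pattern matcher and has
no compile step.

Mutation mentions need no dictionary; three regex families cover the
common notations: protein substitutions `[A-Z]\d+[A-Z]` (word-bounded,
so "T3" and "B12" do not fire), HGVS-like `c.\d+[ACGT]>[ACGT]` and
`p.Aaa123Bbb`, and dbSNP `rs\d+` identifiers.

Gene mentions are marked with their surface form as the concept ID —
no normalization to gene identifiers. Mapping mentions to
organism-specific gene IDs is error-prone and a wrong mapping silently
loses recall; since curation starts from a known gene ID anyway, gene
*search* goes in the opposite direction, expanding the ID to its
keywords. Gene annotations are consequently excluded from concept
postings and serve highlighting only.

## Retrieval

Clauses are ANDed; a clause is satisfied by any member of its
expansion. Concept clauses test concept postings; gene and keyword
clauses test stemmed text tokens, case-insensitively (a multi-word
keyword requires all of its tokens). The species constraint is
implemented through organism concept postings, so MeSH-only species
evidence still drives it. Filters chain conjunctively; a concept filter
admits the concept *or any descendant*, and facet counts use the same
closure — which is what makes every displayed count exactly the
post-filter result size. The filter path is ordered for display and
truncation only; permuting it cannot change the result set (all
conjuncts commute).

Scoring instantiates the classic Lucene similarity with fixed
constants to keep tests deterministic:
`coord · Σ_t √tf · idf² / √|d|`, `idf = 1 + ln(N/(df+1))`; concept
clauses contribute with tf = occurrence count and concept document
frequency. All sort orders break ties by descending PMID, preferring
recent literature. Facets are emitted per vocabulary, top 20 by count
(configurable), count-descending then accession.

## Synthetic data

The fixture generator is first-class code: it emits OBO ontologies,
gene tables and MEDLINE XML whose every planted mention has a recorded
field/offset span.

Construction guarantees that make exact-recovery tests valid:

- term surface forms are `<common word> <unique word>` pairs whose
  unique halves (seeded syllable words) occur in exactly one surface
  and are stem-distinct from each other, the filler vocabulary, and
  the organism names;
- a planted inflection (e.g. the `+s` plural) is used only after
  verifying it stems back onto the entry's match tokens;
- filler text is drawn from a fixed 38-word list disjoint (after
  stemming) from every dictionary surface.

Defaults: 50 documents, 30 terms, ontology depth 4, concept mention
rate 0.7 (per each of three slots per abstract), species mix
rat 0.5 / mouse 0.25 / human 0.25 (reflecting a rat-centric curation
corpus with comparative human/mouse work), mutation rate 0.3, gene
mention rate 0.3. `collision_mode` plants near-miss decoys (bare common
words, upper-cased symbol variants, "T3"/"B12") that must *not* match.

What the generator does not emulate — and what passing tests therefore
do not show about real abstracts: natural English (real text has
ambiguous, nested and discontinuous mentions), term polysemy between
vocabularies, MeSH's own hierarchy, and realistic PMID/date
distributions. The oracle-equivalence results certify the matching
machinery, not corpus-level recall on PubMed.

## Problem sizes

The bundled verification (test suite and `scripts/acceptance.py`) runs
the pipeline at desk scale — corpora of 80–300 documents, ontologies of
12–30 terms, 60–100 random queries — sizes at which brute-force oracles
(exhaustive window scans, per-document predicate evaluation, BFS
closures, sort oracles) remain exact and cheap. All generators and
query samplers are seeded; the acceptance script derives every stream
from `--seed`.

## Numerical and degenerate-input choices

- Scores are plain floats; the oracle comparison tolerance is 1e-9
  relative (pure re-ordering of float sums).
- Empty abstracts, empty MeSH lists, header-only gene tables and empty
  batches are all valid inputs yielding empty outputs.
- Duplicate (surface, concept) pairs deduplicate silently; duplicate
  PMIDs within a parsed batch keep the first occurrence with a warning.
- Obsolete ontology terms are excluded from gazetteers and hierarchy.
- Publication dates index at year granularity (PubMed month/day are
  often absent); missing months/days are preserved as absent.
- `read_by` reports the *latest* reader when several exist (ties by
  insertion order), matching the indicator's purpose of showing current
  ownership.

## Known limitations

- Single-node by design: the distributed store/index architecture this
  emulates is out of scope.
- Dictionary-only gene marking (no statistical NER), so gene-mention
  recall is bounded by the gene table's synonym coverage.
- Ontology expansion follows is_a only; other relations (part_of,
  regulates) are ignored.
- The mutation grammar covers the three common notations only, not the
  full HGVS specification.
- Keyword phrase matching is conjunctive over tokens, not positional:
  a multi-word gene name matches any document containing all its
  tokens, even when not adjacent.
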