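# conceptlit

Concept-based literature search for biocuration. Model-organism database
curators turn findings from papers into structured annotations; the
bottleneck is finding the right abstracts and not re-reading ones already
curated. `conceptlit` is a single-node pipeline that parses MEDLINE/PubMed
citation XML into a versioned article store, compiles stemmed dictionaries
from OBO ontologies and gene tables, tags titles/abstracts/MeSH headings
with ontology concepts, organism names, gene mentions and mutation
patterns, indexes everything, and answers expanded, filterable, ranked
queries — so a curator can ask for a gene ID and a disease-term accession
instead of hand-building a keyword query.

## What it does

**Tagging.** Each vocabulary is compiled into two gazetteers: a
case-insensitive one whose surface forms are lowercased and stemmed with
the Snowball English (Porter2) stemmer ("creatures" → "creatur", so
"kidney diseases" matches "kidney disease"), and a case-sensitive one for
short or internally capitalized symbols ("Retn", "FIZZ3") that would
collide with common words if folded. Matching is leftmost-longest per
vocabulary over token sequences; overlaps across vocabularies are kept.
Mutations are matched by regex families (A123T, c.76A>T, p.Ala123Thr,
rs12345). Gene mentions are deliberately *not* normalized to gene IDs —
a mention is marked with its surface form only, and gene search instead
expands the query.

**Query expansion.** An ontology accession expands to itself plus all
is_a descendants; a gene ID expands to the symbol, name and synonyms of
the gene and its orthologs (e.g. RGD:628781 → ADSF, RSTN, XCP1, FIZZ3,
Retn, resistin); a gene-bearing query with no species constraint gets
the default rat/human/mouse filter.

**Ranking.** Relevance is the classic Lucene-style TF-IDF similarity

```
score(q, d) = coord(q, d) · Σ_t √tf(t, d) · idf(t)² / √|d|,
idf(t) = 1 + ln(N / (df(t) + 1))
```

with `coord` the fraction of query clauses matched. Results can also be
sorted by publication year or PMID (ties always break by descending
PMID). Every facet count shown with the results equals exactly the
number of articles that remain if that concept filter is applied.

**Store.** Articles are keyed by the zero-padded, character-reversed
PMID and written with timestamps; the store retains the three most
recent versions per key, so nightly re-runs never need deletes and a
stale write can never shadow a newer payload.

## Worked example

```python
from conceptlit import *
from conceptlit.tagger import build_organism_dictionary, tag_article

obo = """format-version: 1.2
ontology: rdo

[Term]
id: RDO:0000001
name: urinary system disease

[Term]
id: RDO:0000692
name: kidney diseases
is_a: RDO:0000001

[Term]
id: RDO:0000693
name: chronic kidney diseases
is_a: RDO:0000692
"""
disease = compile_dictionary(terms=parse_obo(obo, "disease"),
                             vocabulary="disease")
record = ArticleRecord(
    pmid=24716958,
    title="Resistin and chronic kidney disease in rats",
    abstract="Chronic kidney diseases were induced in rats carrying the "
             "A123T variant. Retn expression increased.",
    pub_date=PubDate(2014),
)
gene_table = parse_gene_table(fixture_gene_table())
doc = tag_article(record, [disease], build_organism_dictionary(),
                  build_gene_dictionary(gene_table))
print("store key:", make_store_key(record.pmid))
for a in doc.annotations:
    print(f"  {a.field:9s} [{a.start:3d},{a.end:3d})  {a.vocabulary:9s} "
          f"{a.concept_id:12s} {a.matched_text!r}")
print("Retn expands to:",
      sorted(expand_gene_clause("RGD:628781", gene_table).expansion))
print("descendants of RDO:0000692:",
      sorted(descendants(disease, "RDO:0000692")))
```

prints

```
store key: 859617420
  abstract  [  0, 23)  disease   RDO:0000693  'Chronic kidney diseases'
  abstract  [ 40, 44)  organism  TAXON:10116  'rats'
  abstract  [ 58, 63)  mutation  A123T        'A123T'
  abstract  [ 73, 77)  gene      Retn         'Retn'
  title     [  0,  8)  gene      resistin     'Resistin'
  title     [ 13, 35)  disease   RDO:0000693  'chronic kidney disease'
  title     [ 39, 43)  organism  TAXON:10116  'rats'
```

plus the gene expansion `['ADSF', 'FIZZ3', 'RSTN', 'Retn', 'XCP1',
'resistin']` and the descendant closure `['RDO:0000692', 'RDO:0000693']`.
Note how the singular title phrase matched the plural dictionary entry
through stemming, how the mention of the *more specific* term
(RDO:0000693) suppressed the shorter nested match, how the mutation and
the gene symbol were caught without any dictionary of mutations, and how
the gene annotations carry surface forms ("Retn", "resistin"), not IDs.

## Command line

```
conceptlit gen --seed 5 --docs 30 --out fix/           # synthetic fixtures
conceptlit load fix/corpus.xml --store articles.db --timestamp 1
conceptlit build-dicts --obo fix/ontology.obo --genes fix/genes.tsv --out dicts.json
conceptlit tag --store articles.db --dicts dicts.json --out tags.jsonl
conceptlit index --store articles.db --tags tags.jsonl --out index.json
conceptlit query --index index.json --dicts dicts.json \
    --genes fix/genes.tsv --gene RGD:628781 --term TST:0000001 \
    --filter years:2000-2010 --sort relevance
conceptlit log --log-file events.jsonl --event read --pmid 1001 --curator alice
```

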