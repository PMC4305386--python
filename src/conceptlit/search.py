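"""Inverted index, query expansion and ranked, faceted retrieval.

The index holds stemmed-token postings (with term frequencies) over
title+abstract text, concept postings from the tagger's annotations,
document token lengths and publication years. A query is a conjunction
of clauses, each clause a disjunction of its expansion: an ontology
accession expands to itself plus all is_a descendants, a gene ID
expands to symbol, name and synonyms of the gene and its orthologs
(matched case-insensitively as keywords — gene mentions are not
concept-indexed), and a gene-bearing query with no explicit species
constraint gets the default rat/human/mouse filter appended.

Relevance follows the classic Lucene-style TF-IDF similarity:

    score(q, d) = coord(q, d) * sum_t sqrt(tf(t, d)) * idf(t)^2 / sqrt(|d|)

with idf(t) = 1 + ln(n_docs / (df(t) + 1)) and coord the fraction of
query clauses the document matches. Facet counts over the result set
predict exactly how many articles remain if the facet's concept filter
is applied (descendants included), which is what makes the filter zone's
numbers trustworthy during triage.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .dictionaries import CompiledDictionary, GeneRecord, UnknownAccessionError, \
    descendants, stem_token
from .medline import ArticleRecord
from .tagger import DEFAULT_SPECIES, GENE_VOCABULARY, TaggedDocument, tokenize

SORT_ORDERS = ("relevance", "pub_date", "pmid")
DEFAULT_FACET_TOP_N = 20


class IndexingError(RuntimeError):
    """A tagged document had no retrievable article record."""


class UnknownGeneError(KeyError):
    """Gene ID absent from the gene table."""


@dataclass
class InvertedIndex:
    text_postings: dict[str, dict[int, int]] = field(default_factory=dict)
    concept_postings: dict[str, set[int]] = field(default_factory=dict)
    concept_counts: dict[int, dict[str, int]] = field(default_factory=dict)
    concept_vocab: dict[str, str] = field(default_factory=dict)
    doc_lengths: dict[int, int] = field(default_factory=dict)
    doc_dates: dict[int, int] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)

    def df(self, token: str) -> int:
        return len(self.text_postings.get(token, ()))

    def tf(self, token: str, pmid: int) -> int:
        return self.text_postings.get(token, {}).get(pmid, 0)

    def idf(self, token: str) -> float:
        return 1.0 + math.log(self.n_docs / (self.df(token) + 1))

    def concept_idf(self, concept_id: str) -> float:
        df = len(self.concept_postings.get(concept_id, ()))
        return 1.0 + math.log(self.n_docs / (df + 1))


@dataclass(frozen=True)
class QueryClause:
    kind: str                     # keyword | concept | gene
    raw: str
    expansion: frozenset[str]


@dataclass
class Filter:
    kind: str                     # concept | date_range
    concept_id: str | None = None
    year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if (self.concept_id is None) == (self.year_range is None):
            raise ValueError("exactly one of concept_id / year_range must be set")


@dataclass
class QueryCondition:
    clauses: list[QueryClause] = field(default_factory=list)
    species_filter: frozenset[str] = frozenset()
    filter_path: list[Filter] = field(default_factory=list)
    species_explicit: bool = False


@dataclass(frozen=True)
class FacetCount:
    concept_id: str
    count: int


@dataclass
class RankedResult:
    pmid: int
    score: float
    pub_year: int
    matched_concepts: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Index construction
# ---------------------------------------------------------------------------

def text_tokens(record: ArticleRecord) -> list[str]:
    """Stemmed lowercased tokens of title + abstract (index vocabulary)."""
    tokens = tokenize(record.title) + tokenize(record.abstract)
    return [stem_token(t.text.lower()) for t in tokens]


def build_index(tagged_docs: Iterable[TaggedDocument],
                records: Callable[[int], ArticleRecord | None] | Mapping[int, ArticleRecord],
                ) -> InvertedIndex:
    """Index text tokens and concept annotations for a tagged corpus.

    ``records`` maps a PMID to its stored article (a mapping or a getter
    such as ``ArticleStore.get_article``). Gene annotations are excluded
    from concept postings: gene search is keyword-based by design.
    """
    getter = records.get if isinstance(records, Mapping) else records
    index = InvertedIndex()
    for doc in tagged_docs:
        record = getter(doc.pmid)
        if record is None:
            raise IndexingError(f"no stored article for PMID {doc.pmid}")
        tokens = text_tokens(record)
        index.doc_lengths[doc.pmid] = len(tokens)
        index.doc_dates[doc.pmid] = record.pub_date.year
        for token, tf in Counter(tokens).items():
            index.text_postings.setdefault(token, {})[doc.pmid] = tf
        counts: dict[str, int] = {}
        for ann in doc.annotations:
            if ann.vocabulary == GENE_VOCABULARY:
                continue
            index.concept_postings.setdefault(ann.concept_id, set()).add(doc.pmid)
            index.concept_vocab[ann.concept_id] = ann.vocabulary
            counts[ann.concept_id] = counts.get(ann.concept_id, 0) + 1
        index.concept_counts[doc.pmid] = counts
    return index


# ---------------------------------------------------------------------------
# Query expansion
# ---------------------------------------------------------------------------

def expand_concept_clause(accession: str,
                          dictionaries: Iterable[CompiledDictionary]) -> QueryClause:
    """Ontology clause: the accession plus its full descendant closure."""
    for dictionary in dictionaries:
        if accession in dictionary.descendants_index:
            return QueryClause(kind="concept", raw=accession,
                               expansion=frozenset(descendants(dictionary, accession)))
    raise UnknownAccessionError(f"accession {accession!r} unknown to all dictionaries")


def expand_gene_clause(gene_id: str,
                       gene_table: Sequence[GeneRecord]) -> QueryClause:
    """Gene clause: symbol, name and synonyms of the gene and its orthologs.

    Keywords are deduplicated case-insensitively and matched against text
    postings (genes are not concept-indexed).
    """
    import logging
    by_id = {g.gene_id: g for g in gene_table}
    if gene_id not in by_id:
        raise UnknownGeneError(f"gene {gene_id!r} not in table")
    keywords: dict[str, str] = {}

    def admit(gene: GeneRecord) -> None:
        for kw in [gene.symbol, gene.name, *gene.synonyms]:
            if kw and kw.lower() not in keywords:
                keywords[kw.lower()] = kw

    gene = by_id[gene_id]
    admit(gene)
    for orth_id in gene.ortholog_ids:
        if orth_id in by_id:
            admit(by_id[orth_id])
        else:
            logging.getLogger("conceptlit.search").warning(
                "ortholog %s of %s not in table; skipped", orth_id, gene_id)
    return QueryClause(kind="gene", raw=gene_id,
                       expansion=frozenset(keywords.values()))


def keyword_clause(text: str) -> QueryClause:
    return QueryClause(kind="keyword", raw=text, expansion=frozenset([text]))


def apply_default_species(condition: QueryCondition,
                          default: Iterable[str] = DEFAULT_SPECIES) -> QueryCondition:
    """Append the rat/human/mouse constraint to gene-bearing queries.

    An explicitly set species filter always wins; keyword-only queries
    are left unconstrained.
    """
    has_gene = any(c.kind == "gene" for c in condition.clauses)
    if has_gene and not condition.species_explicit and not condition.species_filter:
        condition.species_filter = frozenset(default)
    return condition


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _keyword_match_tokens(keyword: str, index: InvertedIndex,
                          pmid: int) -> list[str] | None:
    """Stemmed tokens of a keyword if every one occurs in the document."""
    tokens = [stem_token(t.text.lower()) for t in tokenize(keyword)]
    if tokens and all(index.tf(tok, pmid) > 0 for tok in tokens):
        return tokens
    return None


def clause_matches(clause: QueryClause, pmid: int, index: InvertedIndex) -> bool:
    """A clause is satisfied by any member of its expansion."""
    if clause.kind == "concept":
        return any(pmid in index.concept_postings.get(acc, ())
                   for acc in clause.expansion)
    return any(_keyword_match_tokens(kw, index, pmid) is not None
               for kw in clause.expansion)


def _concept_filter_accessions(flt: Filter,
                               dictionaries: Iterable[CompiledDictionary] | None
                               ) -> set[str]:
    accs = {flt.concept_id}
    for dictionary in dictionaries or ():
        if flt.concept_id in dictionary.descendants_index:
            accs |= descendants(dictionary, flt.concept_id)
            break
    return accs


def filter_matches(flt: Filter, pmid: int, index: InvertedIndex,
                   dictionaries: Iterable[CompiledDictionary] | None = None) -> bool:
    if flt.kind == "date_range":
        lo, hi = flt.year_range
        return lo <= index.doc_dates.get(pmid, 0) <= hi
    accs = _concept_filter_accessions(flt, dictionaries)
    return any(pmid in index.concept_postings.get(a, ()) for a in accs)


def score(condition: QueryCondition, pmid: int, index: InvertedIndex) -> float:
    """TF-IDF similarity of one matching document (see module docstring)."""
    length = index.doc_lengths.get(pmid, 0)
    norm = 1.0 / math.sqrt(length) if length else 0.0
    total = 0.0
    matching_clauses = 0
    for clause in condition.clauses:
        clause_score = 0.0
        if clause.kind == "concept":
            for acc in clause.expansion:
                tf = index.concept_counts.get(pmid, {}).get(acc, 0)
                if tf:
                    clause_score += math.sqrt(tf) * index.concept_idf(acc) ** 2
        else:
            matched_tokens: set[str] = set()
            for kw in clause.expansion:
                tokens = _keyword_match_tokens(kw, index, pmid)
                if tokens:
                    matched_tokens.update(tokens)
            for tok in matched_tokens:
                clause_score += math.sqrt(index.tf(tok, pmid)) * index.idf(tok) ** 2
        if clause_score > 0:
            matching_clauses += 1
            total += clause_score
    if not condition.clauses or matching_clauses == 0:
        return 0.0
    coord = matching_clauses / len(condition.clauses)
    return coord * total * norm


def evaluate(condition: QueryCondition, index: InvertedIndex,
             dictionaries: Iterable[CompiledDictionary] | None = None,
             facet_top_n: int = DEFAULT_FACET_TOP_N,
             ) -> tuple[list[RankedResult], list[FacetCount]]:
    """Evaluate a fully expanded condition against the index.

    Returns relevance-sorted results and the facet counts over the final
    result set (per vocabulary, top ``facet_top_n``, count-descending).
    Every facet's count equals the exact result-set size its concept
    filter would produce.
    """
    dictionaries = list(dictionaries or ())
    result_pmids = []
    for pmid in index.doc_lengths:
        if not all(clause_matches(c, pmid, index) for c in condition.clauses):
            continue
        if condition.species_filter and not any(
                pmid in index.concept_postings.get(t, ())
                for t in condition.species_filter):
            continue
        if not all(filter_matches(f, pmid, index, dictionaries)
                   for f in condition.filter_path):
            continue
        result_pmids.append(pmid)

    results = [
        RankedResult(
            pmid=pmid,
            score=score(condition, pmid, index),
            pub_year=index.doc_dates.get(pmid, 0),
            matched_concepts=sorted(
                index.concept_counts.get(pmid, {}).items(),
                key=lambda kv: (-kv[1], kv[0])),
        )
        for pmid in result_pmids
    ]
    results = sort_results(results, "relevance")
    facets = compute_facets(result_pmids, index, dictionaries, facet_top_n)
    return results, facets


def compute_facets(result_pmids: Sequence[int], index: InvertedIndex,
                   dictionaries: Iterable[CompiledDictionary] | None = None,
                   top_n: int = DEFAULT_FACET_TOP_N) -> list[FacetCount]:
    """Per-vocabulary top-N facet counts with descendant-closed semantics."""
    result_set = set(result_pmids)
    present: set[str] = set()
    for pmid in result_set:
        present.update(index.concept_counts.get(pmid, ()))
    counted: list[tuple[str, str, int]] = []
    dictionaries = list(dictionaries or ())
    for concept_id in present:
        flt = Filter(kind="concept", concept_id=concept_id)
        accs = _concept_filter_accessions(flt, dictionaries)
        count = sum(
            1 for pmid in result_set
            if any(pmid in index.concept_postings.get(a, ()) for a in accs)
        )
        if count:
            counted.append((index.concept_vocab.get(concept_id, ""),
                            concept_id, count))
    facets: list[FacetCount] = []
    by_vocab: dict[str, list[tuple[str, int]]] = {}
    for vocab, concept_id, count in counted:
        by_vocab.setdefault(vocab, []).append((concept_id, count))
    for vocab in sorted(by_vocab):
        ranked = sorted(by_vocab[vocab], key=lambda kv: (-kv[1], kv[0]))
        facets.extend(FacetCount(concept_id=c, count=k)
                      for c, k in ranked[:top_n])
    return facets


def sort_results(results: Sequence[RankedResult], order: str) -> list[RankedResult]:
    """relevance: score desc; pub_date: year desc; pmid: pmid desc.

    All ties break by descending PMID (newest identifier first).
    """
    if order == "relevance":
        return sorted(results, key=lambda r: (-r.score, -r.pmid))
    if order == "pub_date":
        return sorted(results, key=lambda r: (-r.pub_year, -r.pmid))
    if order == "pmid":
        return sorted(results, key=lambda r: -r.pmid)
    raise ValueError(f"unknown sort order {order!r}; expected one of {SORT_ORDERS}")


def apply_filter(condition: QueryCondition, flt: Filter) -> QueryCondition:
    """Append one filter to the path (returns a new condition)."""
    return QueryCondition(
        clauses=list(condition.clauses),
        species_filter=condition.species_filter,
        filter_path=[*condition.filter_path, flt],
        species_explicit=condition.species_explicit,
    )


def truncate_filters(condition: QueryCondition, keep: int) -> QueryCondition:
    """Remove filters by truncating the path after ``keep`` entries."""
    return QueryCondition(
        clauses=list(condition.clauses),
        species_filter=condition.species_filter,
        filter_path=list(condition.filter_path[:keep]),
        species_explicit=condition.species_explicit,
    )
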