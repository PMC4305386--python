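"""Index construction, query expansion, evaluation, scoring and facets."""

from __future__ import annotations

import math
import random
from collections import Counter, deque

import pytest

from conceptlit import (
    ArticleRecord,
    Filter,
    GeneRecord,
    QueryCondition,
    UnknownAccessionError,
    UnknownGeneError,
    apply_default_species,
    apply_filter,
    build_index,
    evaluate,
    expand_concept_clause,
    expand_gene_clause,
    keyword_clause,
    score,
    sort_results,
    stem_token,
    tokenize,
    truncate_filters,
)
from conceptlit.search import IndexingError, RankedResult
from conceptlit.tagger import GENE_VOCABULARY, TaggedDocument


# ---------------------------------------------------------------------------
# Independent oracle: per-document predicate evaluation on raw data
# ---------------------------------------------------------------------------

def doc_stemmed_tokens(record):
    return [stem_token(t.text.lower())
            for t in tokenize(record.title) + tokenize(record.abstract)]


def doc_concepts(tagged_doc):
    return {a.concept_id for a in tagged_doc.annotations
            if a.vocabulary != GENE_VOCABULARY}


def closure(accession, terms):
    children = {}
    for t in terms:
        for p in t.parent_accessions:
            children.setdefault(p, set()).add(t.accession)
    seen, queue = {accession}, deque([accession])
    while queue:
        for nxt in children.get(queue.popleft(), ()):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen


def brute_force_evaluate(condition, records, tagged_by_pmid, terms):
    """Per-document boolean predicate evaluation straight off the data."""
    hits = set()
    for pmid, record in records.items():
        concepts = doc_concepts(tagged_by_pmid[pmid])
        tokens = set(doc_stemmed_tokens(record))

        def clause_ok(clause):
            if clause.kind == "concept":
                return bool(clause.expansion & concepts)
            for kw in clause.expansion:
                kw_tokens = [stem_token(t.text.lower()) for t in tokenize(kw)]
                if kw_tokens and all(t in tokens for t in kw_tokens):
                    return True
            return False

        def filter_ok(flt):
            if flt.kind == "date_range":
                lo, hi = flt.year_range
                return lo <= record.pub_date.year <= hi
            return bool(closure(flt.concept_id, terms) & concepts)

        if (all(clause_ok(c) for c in condition.clauses)
                and (not condition.species_filter
                     or condition.species_filter & concepts)
                and all(filter_ok(f) for f in condition.filter_path)):
            hits.add(pmid)
    return hits


def straight_line_score(condition, pmid, records, tagged_by_pmid, all_pmids):
    """Independent reimplementation of the TF-IDF similarity formula."""
    n_docs = len(all_pmids)
    record = records[pmid]
    tokens = doc_stemmed_tokens(record)
    tf_text = Counter(tokens)
    concept_tf = Counter(a.concept_id for a in tagged_by_pmid[pmid].annotations
                         if a.vocabulary != GENE_VOCABULARY)

    def text_df(tok):
        return sum(1 for p in all_pmids
                   if tok in set(doc_stemmed_tokens(records[p])))

    def concept_df(acc):
        return sum(1 for p in all_pmids if acc in doc_concepts(tagged_by_pmid[p]))

    total, matching = 0.0, 0
    for clause in condition.clauses:
        s = 0.0
        if clause.kind == "concept":
            for acc in clause.expansion:
                if concept_tf[acc]:
                    idf = 1 + math.log(n_docs / (concept_df(acc) + 1))
                    s += math.sqrt(concept_tf[acc]) * idf * idf
        else:
            matched = set()
            for kw in clause.expansion:
                kw_toks = [stem_token(t.text.lower()) for t in tokenize(kw)]
                if kw_toks and all(tf_text[t] for t in kw_toks):
                    matched.update(kw_toks)
            for tok in matched:
                idf = 1 + math.log(n_docs / (text_df(tok) + 1))
                s += math.sqrt(tf_text[tok]) * idf * idf
        if s > 0:
            matching += 1
            total += s
    if not matching:
        return 0.0
    coord = matching / len(condition.clauses)
    return coord * total / math.sqrt(len(tokens))


# ---------------------------------------------------------------------------
# build_index
# ---------------------------------------------------------------------------

class TestBuildIndex:
    def test_term_frequency_counted(self):
        record = ArticleRecord(pmid=1, title="x", abstract="kidney kidney")
        index = build_index([TaggedDocument(pmid=1)], {1: record})
        assert index.text_postings["kidney"] == {1: 2}
        assert index.doc_lengths[1] == 3
        assert index.n_docs == 1

    def test_empty_corpus(self):
        index = build_index([], {})
        assert index.n_docs == 0

    def test_missing_record_raises_with_pmid(self):
        with pytest.raises(IndexingError, match="77"):
            build_index([TaggedDocument(pmid=77)], {})

    def test_postings_equal_brute_force_recount(self, corpus_bundle):
        index = corpus_bundle["index"]
        records = corpus_bundle["records"]
        for token, postings in index.text_postings.items():
            expected = {p: Counter(doc_stemmed_tokens(records[p]))[token]
                        for p in records
                        if Counter(doc_stemmed_tokens(records[p]))[token]}
            assert postings == expected
        for doc in corpus_bundle["tagged"]:
            assert doc_concepts(doc) == {
                c for c, pmids in index.concept_postings.items()
                if doc.pmid in pmids}

    def test_gene_annotations_not_concept_indexed(self, corpus_bundle):
        index = corpus_bundle["index"]
        gene_surfaces = {e.concept_id
                         for e in corpus_bundle["gene_dict"].entries}
        assert not gene_surfaces & set(index.concept_postings)


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

class TestExpansion:
    def test_leaf_expands_to_itself(self, corpus_bundle):
        terms = corpus_bundle["terms"]
        index = corpus_bundle["disease"].descendants_index
        leaf = next(t.accession for t in terms
                    if index[t.accession] == {t.accession})
        clause = expand_concept_clause(leaf, [corpus_bundle["disease"]])
        assert clause.expansion == {leaf}

    def test_root_expansion_size(self, corpus_bundle):
        root = corpus_bundle["terms"][0].accession
        clause = expand_concept_clause(root, [corpus_bundle["disease"]])
        assert clause.expansion == closure(root, corpus_bundle["terms"])
        assert root in clause.expansion

    def test_unknown_accession(self, corpus_bundle):
        with pytest.raises(UnknownAccessionError):
            expand_concept_clause("NOPE:0000001", [corpus_bundle["disease"]])

    def test_retn_expands_to_table1_keywords(self, gene_table):
        clause = expand_gene_clause("RGD:628781", gene_table)
        assert {k.lower() for k in clause.expansion} == {
            "adsf", "rstn", "xcp1", "fizz3", "retn", "resistin"}

    def test_gene_without_synonyms(self):
        table = [GeneRecord("RGD:1", "Abc1", "abcase")]
        clause = expand_gene_clause("RGD:1", table)
        assert clause.expansion == {"Abc1", "abcase"}

    def test_ortholog_union_equals_brute_force(self):
        table = [
            GeneRecord("RGD:1", "Abc1", "abcase", ["AB1"], ["MGI:1", "HGNC:1"]),
            GeneRecord("MGI:1", "Abc1m", "mouse abcase", ["MAB"]),
            GeneRecord("HGNC:1", "ABC1", "human abcase"),
        ]
        clause = expand_gene_clause("RGD:1", table)
        expected = set()
        for g in table:
            expected |= {g.symbol, g.name, *g.synonyms}
        deduped = {}
        for kw in expected:
            deduped.setdefault(kw.lower(), kw)
        assert {k.lower() for k in clause.expansion} == set(deduped)

    def test_unknown_ortholog_skipped_with_warning(self, caplog):
        table = [GeneRecord("RGD:1", "Abc1", "abcase", [], ["GONE:9"])]
        clause = expand_gene_clause("RGD:1", table)
        assert clause.expansion == {"Abc1", "abcase"}

    def test_unknown_gene_raises(self, gene_table):
        with pytest.raises(UnknownGeneError):
            expand_gene_clause("RGD:0", gene_table)


class TestDefaultSpecies:
    def test_gene_query_gets_three_species(self, gene_table):
        cond = QueryCondition(clauses=[expand_gene_clause("RGD:628781",
                                                          gene_table)])
        cond = apply_default_species(cond)
        assert cond.species_filter == {
            "TAXON:10116", "TAXON:9606", "TAXON:10090"}

    def test_explicit_species_wins(self, gene_table):
        cond = QueryCondition(
            clauses=[expand_gene_clause("RGD:628781", gene_table)],
            species_filter=frozenset({"TAXON:10116"}), species_explicit=True)
        assert apply_default_species(cond).species_filter == {"TAXON:10116"}

    def test_keyword_only_query_unconstrained(self):
        cond = QueryCondition(clauses=[keyword_clause("kidney")])
        assert apply_default_species(cond).species_filter == frozenset()


# ---------------------------------------------------------------------------
# Evaluation, scoring, sorting, filtering
# ---------------------------------------------------------------------------

def _tagged_by_pmid(bundle):
    return {d.pmid: d for d in bundle["tagged"]}


def _random_condition(rng, bundle):
    terms = bundle["terms"]
    cond = QueryCondition()
    for _ in range(rng.randrange(1, 4)):
        kind = rng.choice(("concept", "keyword", "gene"))
        if kind == "concept":
            acc = rng.choice(terms).accession
            cond.clauses.append(
                expand_concept_clause(acc, [bundle["disease"]]))
        elif kind == "gene":
            gene = rng.choice(bundle["genes"])
            cond.clauses.append(expand_gene_clause(gene.gene_id,
                                                   bundle["genes"]))
        else:
            from conceptlit.fixtures import FILLER_WORDS
            cond.clauses.append(keyword_clause(rng.choice(FILLER_WORDS)))
    if rng.random() < 0.3:
        cond.species_filter = frozenset(
            rng.sample(["TAXON:10116", "TAXON:10090", "TAXON:9606"],
                       rng.randrange(1, 3)))
        cond.species_explicit = True
    for _ in range(rng.randrange(0, 3)):
        if rng.random() < 0.5:
            cond.filter_path.append(Filter(
                "concept", concept_id=rng.choice(terms).accession))
        else:
            lo = rng.randrange(1990, 2020)
            cond.filter_path.append(Filter(
                "date_range", year_range=(lo, lo + rng.randrange(0, 15))))
    return cond


class TestEvaluate:
    def test_absent_concept_gives_empty_results_and_facets(self, corpus_bundle):
        # an accession in the hierarchy but never planted: use an
        # expansion replaced with a fresh frozenset
        from conceptlit.search import QueryClause
        cond = QueryCondition(clauses=[QueryClause(
            "concept", "X:404", frozenset({"X:404"}))])
        results, facets = evaluate(cond, corpus_bundle["index"])
        assert results == [] and facets == []

    def test_planted_concept_count_and_facet_agree(self, corpus_bundle):
        index = corpus_bundle["index"]
        truth = corpus_bundle["truth"]
        # pick a concept planted in >= 1 docs; count from ground truth
        planted = Counter(m.concept_id for pmids in truth.mentions.values()
                          for m in pmids if m.vocabulary == "disease")
        concept, _ = planted.most_common(1)[0]
        expected_docs = {p for p, ms in truth.mentions.items()
                         if any(m.concept_id == concept for m in ms)}
        from conceptlit.search import QueryClause
        cond = QueryCondition(clauses=[QueryClause(
            "concept", concept, frozenset({concept}))])
        results, facets = evaluate(cond, corpus_bundle["index"],
                                   [corpus_bundle["disease"]])
        assert {r.pmid for r in results} == expected_docs

    def test_random_conditions_equal_brute_force(self, corpus_bundle):
        rng = random.Random(99)
        tagged = _tagged_by_pmid(corpus_bundle)
        for _ in range(40):
            cond = _random_condition(rng, corpus_bundle)
            results, _ = evaluate(cond, corpus_bundle["index"],
                                  [corpus_bundle["disease"]])
            expected = brute_force_evaluate(cond, corpus_bundle["records"],
                                            tagged, corpus_bundle["terms"])
            assert {r.pmid for r in results} == expected

    def test_filter_order_permutation_invariance(self, corpus_bundle):
        rng = random.Random(5)
        for _ in range(10):
            cond = _random_condition(rng, corpus_bundle)
            if len(cond.filter_path) < 2:
                continue
            base, _ = evaluate(cond, corpus_bundle["index"],
                               [corpus_bundle["disease"]])
            perm = QueryCondition(
                clauses=cond.clauses,
                species_filter=cond.species_filter,
                filter_path=list(reversed(cond.filter_path)))
            swapped, _ = evaluate(perm, corpus_bundle["index"],
                                  [corpus_bundle["disease"]])
            assert {r.pmid for r in base} == {r.pmid for r in swapped}

    def test_expansion_soundness(self, corpus_bundle):
        """Any doc returned for an accession is tagged with a descendant."""
        tagged = _tagged_by_pmid(corpus_bundle)
        for term in corpus_bundle["terms"][:10]:
            clause = expand_concept_clause(term.accession,
                                           [corpus_bundle["disease"]])
            results, _ = evaluate(QueryCondition(clauses=[clause]),
                                  corpus_bundle["index"])
            for r in results:
                assert clause.expansion & doc_concepts(tagged[r.pmid])

    def test_matched_concepts_sorted_by_count_then_id(self, corpus_bundle):
        cond = QueryCondition(clauses=[expand_concept_clause(
            corpus_bundle["terms"][0].accession, [corpus_bundle["disease"]])])
        results, _ = evaluate(cond, corpus_bundle["index"])
        for r in results:
            key = [(-n, c) for c, n in r.matched_concepts]
            assert key == sorted(key)


class TestFacets:
    def test_facet_counts_are_honest(self, corpus_bundle):
        rng = random.Random(17)
        for _ in range(15):
            cond = _random_condition(rng, corpus_bundle)
            cond.filter_path = []
            _, facets = evaluate(cond, corpus_bundle["index"],
                                 [corpus_bundle["disease"]])
            for facet in facets:
                refined = apply_filter(cond, Filter(
                    "concept", concept_id=facet.concept_id))
                results, _ = evaluate(refined, corpus_bundle["index"],
                                      [corpus_bundle["disease"]])
                assert len(results) == facet.count

    def test_facets_sorted_count_desc_then_id_per_vocab(self, corpus_bundle):
        cond = QueryCondition()
        _, facets = evaluate(cond, corpus_bundle["index"],
                             [corpus_bundle["disease"]])
        index = corpus_bundle["index"]
        by_vocab = {}
        for f in facets:
            by_vocab.setdefault(
                index.concept_vocab.get(f.concept_id, ""), []).append(f)
        for group in by_vocab.values():
            keys = [(-f.count, f.concept_id) for f in group]
            assert keys == sorted(keys)
        assert all(f.count >= 1 for f in facets)


class TestScore:
    def test_tf_ratio_two_to_one(self):
        r1 = ArticleRecord(pmid=1, title="pad",
                           abstract="kidney kidney kidney kidney pad pad pad")
        r2 = ArticleRecord(pmid=2, title="pad",
                           abstract="kidney pad pad pad pad pad pad")
        index = build_index([TaggedDocument(pmid=1), TaggedDocument(pmid=2)],
                            {1: r1, 2: r2})
        cond = QueryCondition(clauses=[keyword_clause("kidney")])
        s1 = score(cond, 1, index)
        s2 = score(cond, 2, index)
        assert s1 > 0 and s2 > 0
        assert s1 / s2 == pytest.approx(2.0, rel=1e-12)

    def test_scores_equal_straight_line_reimplementation(self, corpus_bundle):
        rng = random.Random(7)
        records = corpus_bundle["records"]
        pmids = sorted(records)[:20]
        sub_records = {p: records[p] for p in pmids}
        tagged = {p: d for p, d in _tagged_by_pmid(corpus_bundle).items()
                  if p in sub_records}
        index = build_index(tagged.values(), sub_records)
        for _ in range(15):
            cond = _random_condition(rng, corpus_bundle)
            cond.filter_path, cond.species_filter = [], frozenset()
            results, _ = evaluate(cond, index, [corpus_bundle["disease"]])
            for r in results:
                expected = straight_line_score(cond, r.pmid, sub_records,
                                               tagged, pmids)
                assert r.score == pytest.approx(expected, rel=1e-9)
                assert r.score > 0

    def test_scale_invariance_under_duplication(self, corpus_bundle):
        """Duplicating every document leaves relative order unchanged."""
        records = corpus_bundle["records"]
        pmids = sorted(records)[:10]
        tagged = {p: d for p, d in _tagged_by_pmid(corpus_bundle).items()
                  if p in pmids}
        base_idx = build_index([tagged[p] for p in pmids],
                               {p: records[p] for p in pmids})
        dup_records, dup_tagged = {}, []
        for p in pmids:
            for off in (0, 1_000_000):
                dup_records[p + off] = records[p]
                dup_tagged.append(TaggedDocument(
                    pmid=p + off, annotations=list(tagged[p].annotations)))
        dup_idx = build_index(dup_tagged, dup_records)
        cond = QueryCondition(clauses=[expand_concept_clause(
            corpus_bundle["terms"][0].accession, [corpus_bundle["disease"]])])
        base_rank = [r.pmid for r in evaluate(cond, base_idx)[0]]
        dup_rank = [r.pmid for r in evaluate(cond, dup_idx)[0]
                    if r.pmid < 1_000_000]
        assert base_rank == dup_rank


class TestSortAndFilter:
    def test_tie_breaks_by_descending_pmid(self):
        results = [RankedResult(pmid=11, score=1.0, pub_year=2000),
                   RankedResult(pmid=12, score=1.0, pub_year=2000)]
        assert [r.pmid for r in sort_results(results, "relevance")] == [12, 11]
        assert [r.pmid for r in sort_results(results, "pub_date")] == [12, 11]

    def test_pmid_order_descending(self):
        results = [RankedResult(pmid=p, score=0.5, pub_year=2000)
                   for p in (11, 13, 12)]
        assert [r.pmid for r in sort_results(results, "pmid")] == [13, 12, 11]

    def test_unknown_order_is_usage_error(self):
        with pytest.raises(ValueError):
            sort_results([], "upside_down")

    def test_reference_sort_agreement(self, corpus_bundle):
        rng = random.Random(3)
        results = [RankedResult(pmid=rng.randrange(1, 500),
                                score=rng.choice((0.5, 1.0, 2.0)),
                                pub_year=rng.randrange(1990, 2020))
                   for _ in range(50)]
        assert [r.pmid for r in sort_results(results, "relevance")] == [
            r.pmid for r in sorted(results, key=lambda r: (-r.score, -r.pmid))]
        assert [r.pmid for r in sort_results(results, "pub_date")] == [
            r.pmid for r in sorted(results,
                                   key=lambda r: (-r.pub_year, -r.pmid))]

    def test_apply_then_truncate_restores_original(self, corpus_bundle):
        cond = QueryCondition(clauses=[expand_concept_clause(
            corpus_bundle["terms"][0].accession, [corpus_bundle["disease"]])])
        base, _ = evaluate(cond, corpus_bundle["index"],
                           [corpus_bundle["disease"]])
        refined = apply_filter(cond, Filter("date_range",
                                            year_range=(2000, 2005)))
        restored = truncate_filters(refined, 0)
        again, _ = evaluate(restored, corpus_bundle["index"],
                            [corpus_bundle["disease"]])
        assert {r.pmid for r in base} == {r.pmid for r in again}

    def test_filter_requires_exactly_one_payload(self):
        with pytest.raises(ValueError):
            Filter("concept")
        with pytest.raises(ValueError):
            Filter("concept", concept_id="X:1", year_range=(2000, 2001))
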