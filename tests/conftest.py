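"""Shared fixtures: handcrafted mini-vocabularies and a generated corpus."""

from __future__ import annotations

import pytest

from conceptlit import (
    GeneratorConfig,
    build_index,
    compile_dictionary,
    fixture_gene_table,
    generate_corpus,
    generate_mini_ontology,
    parse_gene_table,
    parse_medline_xml,
    parse_obo,
)
from conceptlit.tagger import (
    build_gene_dictionary,
    build_organism_dictionary,
    tag_article,
)

# Six-term ontology: chain root <- kidney <- chronic-kidney, two other
# children of root, and one obsolete term. Multiword, stemmable names.
SIX_TERM_OBO = """\
format-version: 1.2
ontology: fixture

[Term]
id: FIX:0000001
name: organ disease

[Term]
id: FIX:0000002
name: kidney disease
synonym: "renal disease" EXACT []
synonym: "nephropathy" RELATED []
is_a: FIX:0000001

[Term]
id: FIX:0000003
name: chronic kidney disease
is_a: FIX:0000002

[Term]
id: FIX:0000004
name: heart disease
is_a: FIX:0000001

[Term]
id: FIX:0000005
name: liver disease
is_a: FIX:0000001

[Term]
id: FIX:0000006
name: humours imbalance
is_obsolete: true
is_a: FIX:0000001
"""


@pytest.fixture(scope="session")
def six_terms():
    return parse_obo(SIX_TERM_OBO, "disease")


@pytest.fixture(scope="session")
def disease_dict(six_terms):
    return compile_dictionary(terms=six_terms, vocabulary="disease")


@pytest.fixture(scope="session")
def gene_table():
    return parse_gene_table(fixture_gene_table(seed=0))


@pytest.fixture(scope="session")
def corpus_bundle():
    """Generated 80-doc corpus with dictionaries, tagging and index."""
    cfg = GeneratorConfig(seed=11, n_docs=80, n_terms=25)
    obo, edges = generate_mini_ontology(cfg)
    terms = parse_obo(obo, "disease")
    disease = compile_dictionary(terms=terms, vocabulary="disease")
    genes = parse_gene_table(fixture_gene_table(seed=11))
    gene_dict = build_gene_dictionary(genes)
    organism_dict = build_organism_dictionary()
    xml, truth = generate_corpus(cfg, [disease, gene_dict])
    records = {r.pmid: r for r in parse_medline_xml(xml.encode())}
    tagged = [tag_article(r, [disease], organism_dict, gene_dict)
              for r in records.values()]
    index = build_index(tagged, records)
    return {
        "config": cfg, "terms": terms, "edges": edges, "disease": disease,
        "genes": genes, "gene_dict": gene_dict,
        "organism_dict": organism_dict, "xml": xml, "truth": truth,
        "records": records, "tagged": tagged, "index": index,
    }
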