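"""Dictionary tagging of article fields.

Each field (title, abstract, joined MeSH headings) is tokenized into
letter/digit runs with character offsets. For every vocabulary the
tagger runs the case-insensitive gazetteer over lowercased, stemmed
tokens and the case-sensitive gazetteer over verbatim tokens, taking the
leftmost-longest match; within one vocabulary shorter overlapping
matches are dropped, while matches from different vocabularies may
overlap freely. Mutation mentions are matched by regular-expression
families rather than a dictionary: protein substitutions (A123T),
HGVS-style c./p. expressions and dbSNP rs identifiers.

Gene mentions are deliberately *not* normalized to gene identifiers:
a gene annotation carries the matched surface form itself, and gene
search goes through query-side synonym expansion instead. Mapping a
mention to an organism-specific gene ID is error-prone, and a wrong
mapping would silently lose recall; marking the text is enough for
highlighting.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dictionaries import (
    CASE_INSENSITIVE,
    CASE_SENSITIVE,
    CompiledDictionary,
    GeneRecord,
    compile_dictionary,
    stem_token,
)
from .medline import ArticleRecord

FIELDS = ("title", "abstract", "mesh")
MESH_SEPARATOR = "; "

GENE_VOCABULARY = "gene"
ORGANISM_VOCABULARY = "organism"
MUTATION_VOCABULARY = "mutation"

TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

# Mutation families: protein substitution, HGVS c./p., dbSNP rsID.
MUTATION_PATTERNS = (
    re.compile(r"\b[A-Z]\d+[A-Z]\b"),
    re.compile(r"\bc\.\d+[ACGTacgt]>[ACGTacgt]"),
    re.compile(r"\bp\.[A-Z][a-z]{2}\d+[A-Z][a-z]{2}\b"),
    re.compile(r"\brs\d+\b"),
)

# Bundled organism names: (taxon accession, surface forms).
BUILTIN_ORGANISMS = (
    ("TAXON:10116", ("rat", "Rattus norvegicus")),
    ("TAXON:10090", ("mouse", "Mus musculus")),
    ("TAXON:9606", ("human", "Homo sapiens")),
)
DEFAULT_SPECIES = tuple(taxon for taxon, _ in BUILTIN_ORGANISMS)


@dataclass(frozen=True)
class TokenSpan:
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class Annotation:
    concept_id: str
    vocabulary: str
    field: str
    start: int
    end: int
    matched_text: str


@dataclass
class TaggedDocument:
    pmid: int
    annotations: list[Annotation] = field(default_factory=list)

    @property
    def term_counts(self) -> dict[str, int]:
        return dict(Counter(a.concept_id for a in self.annotations))


def tokenize(field_text: str) -> list[TokenSpan]:
    """Maximal letter/digit runs with 0-based half-open character offsets."""
    return [TokenSpan(m.group(), m.start(), m.end())
            for m in TOKEN_RE.finditer(field_text)]


def mesh_field_text(record: ArticleRecord) -> str:
    """The joined MeSH field; offsets of mesh annotations index this string."""
    return MESH_SEPARATOR.join(record.mesh_terms)


def field_text(record: ArticleRecord, field_name: str) -> str:
    if field_name == "title":
        return record.title
    if field_name == "abstract":
        return record.abstract
    if field_name == "mesh":
        return mesh_field_text(record)
    raise ValueError(f"unknown field {field_name!r}")


def _field_token_groups(record: ArticleRecord,
                        field_name: str) -> list[list[TokenSpan]]:
    """Token runs per matchable unit; MeSH headings tokenize independently
    so no match window spans two headings."""
    if field_name != "mesh":
        return [tokenize(field_text(record, field_name))]
    groups = []
    offset = 0
    for heading in record.mesh_terms:
        groups.append([
            TokenSpan(t.text, t.start + offset, t.end + offset)
            for t in tokenize(heading)
        ])
        offset += len(heading) + len(MESH_SEPARATOR)
    return groups


def _match_tokens_in_group(tokens: Sequence[TokenSpan],
                           dictionary: CompiledDictionary,
                           field_name: str,
                           text: str) -> list[Annotation]:
    """Leftmost-longest gazetteer scan for one vocabulary over one token run."""
    verbatim = [t.text for t in tokens]
    stemmed = [stem_token(t.text.lower()) for t in tokens]
    annotations: list[Annotation] = []
    i = 0
    n = len(tokens)
    max_len = dictionary.max_tokens
    while i < n:
        best_len = 0
        best_concepts: set[str] = set()
        for length in range(min(max_len, n - i), 0, -1):
            concepts = (
                dictionary.lookup(CASE_SENSITIVE, tuple(verbatim[i:i + length]))
                | dictionary.lookup(CASE_INSENSITIVE, tuple(stemmed[i:i + length]))
            )
            if concepts:
                best_len = length
                best_concepts = concepts
                break
        if best_len:
            start = tokens[i].start
            end = tokens[i + best_len - 1].end
            for concept_id in sorted(best_concepts):
                annotations.append(Annotation(
                    concept_id=concept_id,
                    vocabulary=dictionary.vocabulary,
                    field=field_name,
                    start=start,
                    end=end,
                    matched_text=text[start:end],
                ))
            i += best_len
        else:
            i += 1
    return annotations


def _tag_with_dictionary(record: ArticleRecord,
                         dictionary: CompiledDictionary,
                         fields: Iterable[str] = FIELDS) -> list[Annotation]:
    annotations: list[Annotation] = []
    for field_name in fields:
        text = field_text(record, field_name)
        for group in _field_token_groups(record, field_name):
            annotations.extend(
                _match_tokens_in_group(group, dictionary, field_name, text))
    return annotations


def tag_concepts(record: ArticleRecord,
                 dictionaries: Iterable[CompiledDictionary]) -> TaggedDocument:
    """Tag title, abstract and MeSH with every supplied vocabulary."""
    doc = TaggedDocument(pmid=record.pmid)
    for dictionary in dictionaries:
        doc.annotations.extend(_tag_with_dictionary(record, dictionary))
    doc.annotations.sort(key=lambda a: (a.field, a.start, a.end,
                                        a.vocabulary, a.concept_id))
    return doc


def build_organism_dictionary(
        extra: Iterable[tuple[str, Sequence[str]]] = ()) -> CompiledDictionary:
    """Organism gazetteer over the bundled species plus any extras.

    Names are forced into the insensitive (stemmed) gazetteer: species
    common names are ordinary words — "rats" must match "rat" — so the
    short-symbol heuristic does not apply.
    """
    from .dictionaries import OntologyTerm
    terms = [
        OntologyTerm(accession=taxon, name=names[0], synonyms=list(names[1:]))
        for taxon, names in (*BUILTIN_ORGANISMS, *extra)
    ]
    return compile_dictionary(terms=terms, vocabulary=ORGANISM_VOCABULARY,
                              force_case_class=CASE_INSENSITIVE)


def tag_organisms(record: ArticleRecord,
                  organism_dictionary: CompiledDictionary) -> list[Annotation]:
    """Organism mentions in all fields; species MeSH headings count too."""
    return _tag_with_dictionary(record, organism_dictionary)


def tag_mutations(record: ArticleRecord) -> list[Annotation]:
    """Regex-family mutation mentions; concept_id is the matched text."""
    annotations: list[Annotation] = []
    for field_name in FIELDS:
        text = field_text(record, field_name)
        taken: list[tuple[int, int]] = []
        for pattern in MUTATION_PATTERNS:
            for m in pattern.finditer(text):
                if any(m.start() < e and s < m.end() for s, e in taken):
                    continue
                taken.append((m.start(), m.end()))
                annotations.append(Annotation(
                    concept_id=m.group(),
                    vocabulary=MUTATION_VOCABULARY,
                    field=field_name,
                    start=m.start(),
                    end=m.end(),
                    matched_text=m.group(),
                ))
    annotations.sort(key=lambda a: (a.field, a.start, a.end))
    return annotations


def build_gene_dictionary(genes: Iterable[GeneRecord]) -> CompiledDictionary:
    """Gene gazetteer keyed by surface form (mentions are not normalized)."""
    compiled = compile_dictionary(genes=list(genes), vocabulary=GENE_VOCABULARY)
    # Re-key every entry to its own surface form: a gene annotation carries
    # the matched text, never a gene ID.
    rekeyed = compile_dictionary(
        genes=[GeneRecord(gene_id=e.surface_form, symbol=e.surface_form,
                          name="")
               for e in compiled.entries],
        vocabulary=GENE_VOCABULARY,
    )
    return rekeyed


def tag_genes(record: ArticleRecord,
              gene_dictionary: CompiledDictionary) -> list[Annotation]:
    """Mark gene-like text segments for highlighting only.

    Annotations carry the surface form as concept_id; they are never fed
    into concept-indexed search.
    """
    return _tag_with_dictionary(record, gene_dictionary)


def tag_article(record: ArticleRecord,
                concept_dictionaries: Iterable[CompiledDictionary],
                organism_dictionary: CompiledDictionary | None = None,
                gene_dictionary: CompiledDictionary | None = None,
                with_mutations: bool = True) -> TaggedDocument:
    """Full tagging pipeline for one article."""
    doc = tag_concepts(record, concept_dictionaries)
    if organism_dictionary is not None:
        doc.annotations.extend(tag_organisms(record, organism_dictionary))
    if gene_dictionary is not None:
        doc.annotations.extend(tag_genes(record, gene_dictionary))
    if with_mutations:
        doc.annotations.extend(tag_mutations(record))
    doc.annotations.sort(key=lambda a: (a.field, a.start, a.end,
                                        a.vocabulary, a.concept_id))
    return doc
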