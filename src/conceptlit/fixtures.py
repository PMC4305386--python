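"""Deterministic synthetic corpora with planted, ground-truth mentions.

Generates mini-ontologies (OBO 1.2), gene tables and MEDLINE XML article
sets in which every concept, species, gene and mutation mention was
planted at a known character span. Term surface forms are built as
``<common word> <unique word>`` pairs whose unique halves occur nowhere
else, and the filler vocabulary is stem-disjoint from every dictionary
surface, so on a collision-free corpus the tagger's output must equal
the planted ground truth exactly. Planted inflections (plural forms)
are verified against the stemmer at generation time: a variant is only
planted if it stems back onto the dictionary entry.

``collision_mode`` deliberately injects near-miss decoys — bare common
words, case-broken gene symbols, "T3"-style pseudo-mutations — for
negative testing; decoys are crafted to *not* match any entry.

What this emulates: abstracts whose mention layout (span positions,
inflection, case) exercises the tagger; what it does not emulate:
real English syntax, MeSH hierarchy, or realistic term ambiguity.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dictionaries import (
    CompiledDictionary,
    DictionaryEntry,
    GeneRecord,
    OntologyTerm,
    stem_token,
    tokenize_surface,
    write_gene_table,
)
from .medline import ArticleRecord, PubDate, records_to_xml
from .tagger import (
    BUILTIN_ORGANISMS,
    GENE_VOCABULARY,
    MUTATION_VOCABULARY,
    ORGANISM_VOCABULARY,
)

# Filler vocabulary: stem-disjoint from every generated surface form and
# from the bundled organism names (asserted below).
FILLER_WORDS = (
    "within", "between", "observed", "measured", "baseline", "cohort",
    "during", "versus", "overall", "weekly", "sample", "control",
    "groups", "before", "after", "under", "random", "double", "single",
    "method", "result", "showed", "higher", "lower", "total", "period",
    "subject", "trial", "design", "protocol", "effect", "increase",
    "decrease", "signal", "profile", "pattern", "elevated", "reduced",
)

# Common first halves of term names (the non-unique half of a surface).
COMMON_TERM_WORDS = (
    "chronic", "acute", "severe", "progressive", "familial", "primary",
    "secondary", "congenital", "juvenile", "recurrent", "systemic",
    "idiopathic", "persistent",
)

_SYLLABLES = ("ba", "ce", "di", "fo", "gu", "ka", "le", "mi", "no",
              "pu", "ra", "se", "ti", "vo", "zu", "ny", "qo", "wi")


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 50
    n_terms: int = 30
    ontology_depth: int = 4
    mention_rate: float = 0.7
    species_mix: dict[str, float] = field(default_factory=lambda: {
        "TAXON:10116": 0.5,   # rat — the tool's home organism
        "TAXON:10090": 0.25,  # mouse
        "TAXON:9606": 0.25,   # human
    })
    mutation_rate: float = 0.3
    gene_mention_rate: float = 0.3
    collision_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_docs < 0 or self.n_terms < 1 or self.ontology_depth < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.mention_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        total = sum(self.species_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species_mix probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class PlantedMention:
    field: str
    start: int
    end: int
    concept_id: str
    vocabulary: str
    matched_text: str


@dataclass
class GroundTruth:
    records: list[ArticleRecord] = field(default_factory=list)
    mentions: dict[int, list[PlantedMention]] = field(default_factory=dict)
    species: dict[int, set[str]] = field(default_factory=dict)
    mutations: dict[int, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Unique-word supply
# ---------------------------------------------------------------------------

def _unique_words(rng: random.Random, n: int,
                  reserved_stems: set[str]) -> list[str]:
    """n pronounceable nonsense words with pairwise-distinct stems,
    disjoint from ``reserved_stems`` (both the word and its +s plural)."""
    combos = ["".join(c) for c in itertools.product(_SYLLABLES, repeat=3)]
    rng.shuffle(combos)
    out: list[str] = []
    used = set(reserved_stems)
    for word in combos:
        stems = {stem_token(word), stem_token(word + "s")}
        if stems & used:
            continue
        used |= stems
        out.append(word)
        if len(out) == n:
            return out
    raise RuntimeError("unique-word supply exhausted")


def _reserved_stems() -> set[str]:
    reserved = {stem_token(w) for w in FILLER_WORDS}
    reserved |= {stem_token(w) for w in COMMON_TERM_WORDS}
    for _, names in BUILTIN_ORGANISMS:
        for name in names:
            reserved |= {stem_token(t.lower()) for t in tokenize_surface(name)}
    return reserved


# ---------------------------------------------------------------------------
# Mini-ontology
# ---------------------------------------------------------------------------

def generate_mini_ontology(config: GeneratorConfig,
                           prefix: str = "TST"
                           ) -> tuple[str, list[tuple[str, str]]]:
    """Random is_a tree/DAG serialized as OBO 1.2, plus its edge list.

    Returns ``(obo_text, edges)`` with edges as (child, parent) pairs —
    the independent oracle for parser round trips and closure tests.
    """
    rng = random.Random(config.seed)
    n = config.n_terms
    n_synonyms = [rng.choice((0, 1, 1, 2)) for _ in range(n)]
    uniques = iter(_unique_words(rng, n + sum(n_synonyms), _reserved_stems()))

    accessions = [f"{prefix}:{i + 1:07d}" for i in range(n)]
    depth = {0: 0}
    edges: list[tuple[str, str]] = []
    parents: dict[int, list[int]] = {0: []}
    for i in range(1, n):
        shallow = [j for j in range(i) if depth[j] < config.ontology_depth - 1]
        parent = rng.choice(shallow or [0])
        parents[i] = [parent]
        depth[i] = depth[parent] + 1
        if i > 2 and rng.random() < 0.2:  # occasional DAG cross-edge
            extra = rng.choice([j for j in range(i) if j != parent])
            parents[i].append(extra)
        edges.extend((accessions[i], accessions[p]) for p in parents[i])

    stanzas = ["format-version: 1.2", f"ontology: {prefix.lower()}-fixture", ""]
    for i in range(n):
        name = f"{rng.choice(COMMON_TERM_WORDS)} {next(uniques)}"
        stanzas.append("[Term]")
        stanzas.append(f"id: {accessions[i]}")
        stanzas.append(f"name: {name}")
        for _ in range(n_synonyms[i]):
            syn = f"{rng.choice(COMMON_TERM_WORDS)} {next(uniques)}"
            scope = rng.choice(("EXACT", "RELATED", "NARROW"))
            stanzas.append(f'synonym: "{syn}" {scope} []')
        for p in parents.get(i, []):
            stanzas.append(f"is_a: {accessions[p]}")
        stanzas.append("")
    return "\n".join(stanzas), edges


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

RETN = GeneRecord(
    gene_id="RGD:628781",
    symbol="Retn",
    name="resistin",
    synonyms=["ADSF", "RSTN", "XCP1", "FIZZ3"],
    ortholog_ids=[],
)


def fixture_genes(seed: int = 0, n_random: int = 10) -> list[GeneRecord]:
    """The Retn record plus seeded random genes (some with orthologs)."""
    rng = random.Random(seed)
    uniques = _unique_words(rng, n_random, _reserved_stems())
    records = [RETN]
    ids = []
    for i in range(n_random):
        gene_id = f"RGD:{700000 + i}"
        symbol = ("".join(rng.choice("bcdfgklmnprstvz")
                          for _ in range(3)).capitalize() + str(rng.randrange(1, 10)))
        synonyms = [symbol.upper()] if rng.random() < 0.5 else []
        orthologs = [rng.choice(ids)] if ids and rng.random() < 0.4 else []
        records.append(GeneRecord(
            gene_id=gene_id, symbol=symbol, name=uniques[i],
            synonyms=synonyms, ortholog_ids=orthologs,
        ))
        ids.append(gene_id)
    return records


def fixture_gene_table(seed: int = 0, n_random: int = 10) -> str:
    """Tab-delimited gene table text, parseable by ``parse_gene_table``."""
    return write_gene_table(fixture_genes(seed, n_random))


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------

def _verified_inflections(entry: DictionaryEntry) -> list[str]:
    """Surface variants guaranteed to re-match the entry when tagged."""
    variants = [entry.surface_form]
    if entry.case_class == "insensitive":
        plural = entry.surface_form + "s"
        tokens = tuple(stem_token(t.lower()) for t in tokenize_surface(plural))
        if tokens == entry.match_tokens:
            variants.append(plural)
    return variants


def _organism_surfaces(taxon: str) -> list[tuple[str, list[str]]]:
    """(surface, verified variants) for one bundled organism."""
    for tax, names in BUILTIN_ORGANISMS:
        if tax == taxon:
            out = []
            for name in names:
                variants = [name]
                tokens = tokenize_surface(name)
                plural = name + "s"
                base = tuple(stem_token(t.lower()) for t in tokens)
                inflected = tuple(stem_token(t.lower())
                                  for t in tokenize_surface(plural))
                if len(tokens) == 1 and inflected == base:
                    variants.append(plural)
                out.append((name, variants))
            return out
    raise KeyError(taxon)


class _FieldBuilder:
    """Accumulates space-joined chunks, recording planted spans."""

    def __init__(self, field_name: str):
        self.field = field_name
        self._chunks: list[str] = []
        self._pos = 0
        self.mentions: list[PlantedMention] = []

    def add(self, text: str) -> None:
        if self._chunks:
            self._pos += 1
        self._chunks.append(text)
        self._pos += len(text)

    def plant(self, text: str, concept_id: str, vocabulary: str) -> None:
        start = self._pos + (1 if self._chunks else 0)
        self.add(text)
        self.mentions.append(PlantedMention(
            self.field, start, start + len(text), concept_id, vocabulary, text))

    @property
    def text(self) -> str:
        return " ".join(self._chunks)


def _mutation_string(rng: random.Random) -> str:
    kind = rng.randrange(4)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    aa3 = ("Ala", "Arg", "Asp", "Cys", "Gly", "His", "Leu", "Lys",
           "Met", "Phe", "Ser", "Thr", "Val")
    if kind == 0:
        return (rng.choice(aa) + str(rng.randrange(10, 999))
                + rng.choice(aa))
    if kind == 1:
        return (f"c.{rng.randrange(10, 9999)}"
                f"{rng.choice('ACGT')}>{rng.choice('ACGT')}")
    if kind == 2:
        return f"p.{rng.choice(aa3)}{rng.randrange(10, 999)}{rng.choice(aa3)}"
    return f"rs{rng.randrange(1000, 10_000_000)}"


def generate_corpus(config: GeneratorConfig,
                    dictionaries: Sequence[CompiledDictionary],
                    ) -> tuple[str, GroundTruth]:
    """MEDLINE XML article set with planted mentions and its ground truth.

    Concept mentions are drawn from the supplied dictionaries'
    non-organism vocabularies; gene symbols come from a dictionary with
    vocabulary ``gene`` if one is supplied. Each document gets one
    species drawn from ``species_mix``, planted in the abstract (and
    sometimes as a MeSH heading).
    """
    rng = random.Random(config.seed)
    concept_entries = [
        e for d in dictionaries
        if d.vocabulary not in (GENE_VOCABULARY, ORGANISM_VOCABULARY)
        for e in d.entries
    ]
    gene_entries = [
        e for d in dictionaries if d.vocabulary == GENE_VOCABULARY
        for e in d.entries
    ]
    taxa = list(config.species_mix)
    weights = [config.species_mix[t] for t in taxa]

    truth = GroundTruth()
    for i in range(config.n_docs):
        pmid = 1001 + i
        mentions: list[PlantedMention] = []

        title = _FieldBuilder("title")
        for _ in range(rng.randrange(3, 6)):
            title.add(rng.choice(FILLER_WORDS))
        if concept_entries and rng.random() < 0.2 * config.mention_rate:
            entry = rng.choice(concept_entries)
            title.plant(rng.choice(_verified_inflections(entry)),
                        entry.concept_id, entry.vocabulary)

        abstract = _FieldBuilder("abstract")
        taxon = rng.choices(taxa, weights=weights)[0]
        planned: list[tuple[str, str, str]] = []  # (text, concept, vocabulary)
        for _ in range(3):
            if concept_entries and rng.random() < config.mention_rate:
                entry = rng.choice(concept_entries)
                planned.append((rng.choice(_verified_inflections(entry)),
                                entry.concept_id, entry.vocabulary))
        surfaces = _organism_surfaces(taxon)
        for _ in range(rng.randrange(1, 3)):
            _, variants = rng.choice(surfaces)
            planned.append((rng.choice(variants), taxon, ORGANISM_VOCABULARY))
        if rng.random() < config.mutation_rate:
            for _ in range(rng.randrange(1, 3)):
                mut = _mutation_string(rng)
                planned.append((mut, mut, MUTATION_VOCABULARY))
        if gene_entries and rng.random() < config.gene_mention_rate:
            entry = rng.choice(gene_entries)
            planned.append((entry.surface_form, entry.concept_id,
                            entry.vocabulary))
        if config.collision_mode:
            decoys = ["T3", "B12"]
            if concept_entries:
                decoys.append(tokenize_surface(
                    rng.choice(concept_entries).surface_form)[0])
            if gene_entries:
                decoys.append(rng.choice(gene_entries).surface_form.upper()
                              + "Q")
            for decoy in rng.sample(decoys, k=rng.randrange(1, 3)):
                planned.append((decoy, "", ""))

        rng.shuffle(planned)
        for text, concept_id, vocabulary in planned:
            for _ in range(rng.randrange(2, 6)):
                abstract.add(rng.choice(FILLER_WORDS))
            if vocabulary:
                abstract.plant(text, concept_id, vocabulary)
            else:
                abstract.add(text)  # decoy
            if rng.random() < 0.3:
                abstract.add(".")
        for _ in range(rng.randrange(2, 6)):
            abstract.add(rng.choice(FILLER_WORDS))
        abstract.add(".")

        mesh_terms = [f"{rng.choice(FILLER_WORDS)} {rng.choice(FILLER_WORDS)}"
                      for _ in range(rng.randrange(0, 3))]
        mesh_mentions: list[PlantedMention] = []
        if rng.random() < 0.4:
            name, _ = rng.choice(surfaces)
            offset = sum(len(m) + 2 for m in mesh_terms)
            mesh_terms.append(name)
            mesh_mentions.append(PlantedMention(
                "mesh", offset, offset + len(name), taxon,
                ORGANISM_VOCABULARY, name))

        record = ArticleRecord(
            pmid=pmid,
            title=title.text,
            abstract=abstract.text,
            mesh_terms=mesh_terms,
            pub_date=PubDate(
                year=rng.randrange(1990, 2024),
                month=rng.choice((None, rng.randrange(1, 13))),
            ),
            journal=f"journal of {rng.choice(FILLER_WORDS)}",
        )
        mentions = title.mentions + abstract.mentions + mesh_mentions
        truth.records.append(record)
        truth.mentions[pmid] = mentions
        truth.species[pmid] = {m.concept_id for m in mentions
                               if m.vocabulary == ORGANISM_VOCABULARY}
        truth.mutations[pmid] = [m.matched_text for m in mentions
                                 if m.vocabulary == MUTATION_VOCABULARY]
    return records_to_xml(truth.records), truth


def write_medline_xml(records: Iterable[ArticleRecord]) -> str:
    """Serialize records as PubMed article-set XML (round-trip oracle)."""
    return records_to_xml(records)
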