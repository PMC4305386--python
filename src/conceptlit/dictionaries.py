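"""Ontology and gene vocabularies compiled into matching dictionaries.

Two gazetteers per vocabulary, following the classic dictionary-tagging
split: *case-insensitive* entries are lowercased and Snowball-stemmed
token sequences (so "Kidney Diseases" matches "kidney disease"), while
*case-sensitive* entries keep their exact characters (so the gene symbol
"Retn" never fires on "RETN"). A surface form is routed to the sensitive
gazetteer when it is short (≤ 4 characters) or carries an uppercase
letter after its first character — the profile of gene symbols and
abbreviations that would collide with common words if case-folded.

The compiled dictionary also carries the ontology's is_a hierarchy as a
reflexive-transitive descendants index, which is what lets a query for a
parent term ("Kidney Diseases") retrieve articles tagged only with its
children.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Mapping, Union

import networkx as nx
import obonet

from ._porter2 import stem as _porter2_stem

ACCESSION_RE = re.compile(r"^[A-Za-z_]+:\d+$")
_SYNONYM_TEXT_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

CASE_SENSITIVE = "sensitive"
CASE_INSENSITIVE = "insensitive"


class OboParseError(ValueError):
    """Structurally invalid OBO input."""


class GeneTableError(ValueError):
    """Malformed tab-delimited gene table."""


class UnknownAccessionError(KeyError):
    """Accession absent from a dictionary's hierarchy."""


@dataclass
class OntologyTerm:
    accession: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    parent_accessions: list[str] = field(default_factory=list)
    is_obsolete: bool = False


@dataclass
class GeneRecord:
    gene_id: str
    symbol: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    ortholog_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DictionaryEntry:
    surface_form: str
    concept_id: str
    vocabulary: str
    case_class: str
    match_tokens: tuple[str, ...]


@dataclass
class CompiledDictionary:
    """Token-sequence lookup for one vocabulary plus its is_a closure."""

    vocabulary: str
    sensitive: dict[tuple[str, ...], set[str]] = field(default_factory=dict)
    insensitive: dict[tuple[str, ...], set[str]] = field(default_factory=dict)
    descendants_index: dict[str, set[str]] = field(default_factory=dict)
    entries: list[DictionaryEntry] = field(default_factory=list)
    max_tokens: int = 0

    def lookup(self, case_class: str, tokens: tuple[str, ...]) -> set[str]:
        table = self.sensitive if case_class == CASE_SENSITIVE else self.insensitive
        return table.get(tokens, set())


def stem_token(token: str) -> str:
    """English Snowball (Porter2) stem of a single lowercase word."""
    return _porter2_stem(token)


def tokenize_surface(surface: str) -> list[str]:
    """Letter/digit token runs of a surface form (same rule as article text)."""
    return _TOKEN_RE.findall(surface)


def assign_case_class(surface_form: str) -> str:
    """Route a surface form to the sensitive or insensitive gazetteer.

    Sensitive iff the form is at most 4 characters long or any uppercase
    letter occurs after the first character; insensitive otherwise.
    """
    if not surface_form:
        raise ValueError("empty surface form")
    if len(surface_form) <= 4:
        return CASE_SENSITIVE
    if any(c.isupper() for c in surface_form[1:]):
        return CASE_SENSITIVE
    return CASE_INSENSITIVE


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _validate_obo_stanzas(text: str) -> None:
    """Every [Term] stanza must carry an id line; report the stanza's line."""
    stanza_line = None
    has_id = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if stanza_line is not None and not has_id:
                raise OboParseError(
                    f"[Term] stanza at line {stanza_line} has no id"
                )
            stanza_line = lineno if stripped == "[Term]" else None
            has_id = False
        elif stanza_line is not None and stripped.startswith("id:"):
            has_id = True
    if stanza_line is not None and not has_id:
        raise OboParseError(f"[Term] stanza at line {stanza_line} has no id")


def parse_obo(source: Union[bytes, str, Path, BinaryIO],
              vocabulary: str = "") -> list[OntologyTerm]:
    """Parse OBO 1.2 [Term] stanzas into :class:`OntologyTerm` objects.

    All synonym scopes (EXACT, RELATED, ...) are admitted as synonyms;
    obsolete terms are flagged and keep no parents.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
    elif isinstance(source, bytes):
        text = source.decode()
    elif isinstance(source, str):
        text = source
    else:
        raw = source.read()
        text = raw.decode() if isinstance(raw, bytes) else raw
    _validate_obo_stanzas(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    terms: list[OntologyTerm] = []
    for accession, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        synonyms = []
        for line in data.get("synonym", []):
            m = _SYNONYM_TEXT_RE.search(line)
            if m:
                synonyms.append(m.group(1).replace('\\"', '"'))
        terms.append(OntologyTerm(
            accession=accession,
            name=data.get("name", ""),
            synonyms=synonyms,
            parent_accessions=[] if obsolete else list(data.get("is_a", [])),
            is_obsolete=obsolete,
        ))
    terms.sort(key=lambda t: t.accession)
    return terms


def parse_gene_table(source: Union[bytes, str, Path, BinaryIO]) -> list[GeneRecord]:
    """Parse the tab-delimited gene table.

    Columns: gene_id, symbol, name, synonyms (pipe-separated),
    ortholog_ids (pipe-separated). A row with the wrong column count
    raises :class:`GeneTableError` naming the row.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
    elif isinstance(source, bytes):
        text = source.decode()
    elif isinstance(source, str):
        text = source
    else:
        raw = source.read()
        text = raw.decode() if isinstance(raw, bytes) else raw

    lines = [l for l in text.split("\n") if l != ""]
    if not lines:
        return []
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rownum, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != 5:
            raise GeneTableError(
                f"row {rownum}: expected 5 tab-delimited columns, got {len(cols)}"
            )
        gene_id, symbol, name, syn_cell, orth_cell = cols
        if not symbol:
            raise GeneTableError(f"row {rownum}: empty symbol")
        if gene_id in seen:
            raise GeneTableError(f"row {rownum}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        records.append(GeneRecord(
            gene_id=gene_id,
            symbol=symbol,
            name=name,
            synonyms=[s for s in syn_cell.split("|") if s],
            ortholog_ids=[o for o in orth_cell.split("|") if o],
        ))
    return records


def write_gene_table(records: Iterable[GeneRecord]) -> str:
    header = "gene_id\tsymbol\tname\tsynonyms\tortholog_ids"
    rows = [header]
    for r in records:
        rows.append("\t".join([
            r.gene_id, r.symbol, r.name,
            "|".join(r.synonyms), "|".join(r.ortholog_ids),
        ]))
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def _match_tokens(surface: str, case_class: str) -> tuple[str, ...]:
    tokens = tokenize_surface(surface)
    if case_class == CASE_INSENSITIVE:
        tokens = [stem_token(t.lower()) for t in tokens]
    return tuple(tokens)


def _closure_from_edges(nodes: Iterable[str],
                        child_parent_edges: Iterable[tuple[str, str]]
                        ) -> dict[str, set[str]]:
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    for child, parent in child_parent_edges:
        if parent in graph:
            graph.add_edge(parent, child)  # parent -> child for descendants()
    return {n: {n} | nx.descendants(graph, n) for n in graph.nodes}


def compile_dictionary(terms: Iterable[OntologyTerm] | None = None,
                       genes: Iterable[GeneRecord] | None = None,
                       vocabulary: str = "",
                       force_case_class: str | None = None) -> CompiledDictionary:
    """Compile ontology terms or gene records into a matching dictionary.

    One entry per (concept, name-or-synonym) pair. Insensitive entries
    are lowercased and stemmed; sensitive entries keep exact characters.
    Obsolete ontology terms are excluded from both gazetteers and from
    the hierarchy. ``force_case_class`` overrides the automatic routing
    (used for organism names, which are ordinary words at any length).
    For gene dictionaries the descendants index is empty.
    """
    if (terms is None) == (genes is None):
        raise ValueError("provide exactly one of terms or genes")
    surfaces: list[tuple[str, str]] = []  # (surface_form, concept_id)
    descendants_index: dict[str, set[str]] = {}
    if terms is not None:
        terms = list(terms)
        active = [t for t in terms if not t.is_obsolete]
        for term in active:
            for surface in [term.name, *term.synonyms]:
                if surface:
                    surfaces.append((surface, term.accession))
        descendants_index = _closure_from_edges(
            (t.accession for t in active),
            ((t.accession, p) for t in active for p in t.parent_accessions),
        )
    else:
        for gene in genes:
            for surface in [gene.symbol, gene.name, *gene.synonyms]:
                if surface:
                    surfaces.append((surface, gene.gene_id))

    compiled = CompiledDictionary(vocabulary=vocabulary,
                                  descendants_index=descendants_index)
    seen: set[tuple[str, str]] = set()
    for surface, concept_id in surfaces:
        if (surface, concept_id) in seen:
            continue
        seen.add((surface, concept_id))
        case_class = force_case_class or assign_case_class(surface)
        tokens = _match_tokens(surface, case_class)
        if not tokens:
            continue
        entry = DictionaryEntry(surface, concept_id, vocabulary,
                                case_class, tokens)
        compiled.entries.append(entry)
        table = (compiled.sensitive if case_class == CASE_SENSITIVE
                 else compiled.insensitive)
        table.setdefault(tokens, set()).add(concept_id)
        compiled.max_tokens = max(compiled.max_tokens, len(tokens))
    return compiled


def descendants(dictionary: CompiledDictionary, accession: str) -> set[str]:
    """Reflexive-transitive is_a closure below (and including) a term."""
    try:
        return set(dictionary.descendants_index[accession])
    except KeyError:
        raise UnknownAccessionError(
            f"accession {accession!r} not in vocabulary {dictionary.vocabulary!r}"
        ) from None


# ---------------------------------------------------------------------------
# Serialization (CLI round trip)
# ---------------------------------------------------------------------------

def save_dictionaries(dictionaries: Iterable[CompiledDictionary],
                      path: Union[str, Path]) -> None:
    payload = []
    for d in dictionaries:
        payload.append({
            "vocabulary": d.vocabulary,
            "entries": [
                {"surface_form": e.surface_form, "concept_id": e.concept_id,
                 "case_class": e.case_class, "match_tokens": list(e.match_tokens)}
                for e in d.entries
            ],
            "descendants_index": {k: sorted(v)
                                  for k, v in d.descendants_index.items()},
        })
    Path(path).write_text(json.dumps(payload, indent=1))


def load_dictionaries(path: Union[str, Path]) -> list[CompiledDictionary]:
    payload = json.loads(Path(path).read_text())
    out = []
    for blob in payload:
        d = CompiledDictionary(
            vocabulary=blob["vocabulary"],
            descendants_index={k: set(v)
                               for k, v in blob["descendants_index"].items()},
        )
        for e in blob["entries"]:
            entry = DictionaryEntry(e["surface_form"], e["concept_id"],
                                    d.vocabulary, e["case_class"],
                                    tuple(e["match_tokens"]))
            d.entries.append(entry)
            table = (d.sensitive if entry.case_class == CASE_SENSITIVE
                     else d.insensitive)
            table.setdefault(entry.match_tokens, set()).add(entry.concept_id)
            d.max_tokens = max(d.max_tokens, len(entry.match_tokens))
        out.append(d)
    return out
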