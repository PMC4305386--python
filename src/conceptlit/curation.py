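"""Curator interaction log and result decorations.

Every curator action on a result — opening an abstract, importing the
article into the curation database, bucketing a term, following a
full-text link — is appended to a durable JSON-lines log. Query results
are then decorated with the three triage indicators: whether the
article is already in the reference database, which annotation aspects
it carries (D = disease; C/F/P = the GO aspects), and who last read it.
The read-by indicator is what prevents two curators from unknowingly
re-reading the same abstract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

EVENT_KINDS = ("read", "import", "add_term", "fulltext")

DEFAULT_ASPECT_LETTERS = {
    "disease": "D",
    "go_component": "C",
    "go_function": "F",
    "go_process": "P",
}


@dataclass(frozen=True)
class CurationEvent:
    event_kind: str
    pmid: int
    curator: str
    timestamp: int
    concept_id: str | None = None

    def __post_init__(self) -> None:
        if self.event_kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.event_kind!r}")
        if self.event_kind == "add_term" and not self.concept_id:
            raise ValueError("add_term events require a concept_id")


@dataclass
class ResultDecoration:
    pmid: int
    in_database: bool = False
    aspects: set[str] = field(default_factory=set)
    read_by: tuple[str, int] | None = None


class CurationLog:
    """Append-only event log, optionally persisted as JSON lines."""

    def __init__(self, path: Union[str, Path, None] = None):
        self._path = Path(path) if path is not None else None
        self._events: list[CurationEvent] = []
        if self._path is not None and self._path.exists():
            for line in self._path.read_text().splitlines():
                if line.strip():
                    self._events.append(CurationEvent(**json.loads(line)))

    @property
    def events(self) -> list[CurationEvent]:
        return list(self._events)

    def log_event(self, event: CurationEvent) -> bool:
        """Append one event; duplicates are allowed (idempotent replays)."""
        self._events.append(event)
        if self._path is not None:
            with self._path.open("a") as fh:
                fh.write(json.dumps({
                    "event_kind": event.event_kind,
                    "pmid": event.pmid,
                    "curator": event.curator,
                    "timestamp": event.timestamp,
                    "concept_id": event.concept_id,
                }) + "\n")
        return True

    def read_by(self, pmid: int) -> tuple[str, int] | None:
        """Latest read event for the article, or None if never opened."""
        best: tuple[str, int] | None = None
        for event in self._events:
            if event.event_kind == "read" and event.pmid == pmid:
                if best is None or event.timestamp >= best[1]:
                    best = (event.curator, event.timestamp)
        return best


def log_event(log: CurationLog, event: CurationEvent) -> bool:
    return log.log_event(event)


def read_by(log: CurationLog, pmid: int) -> tuple[str, int] | None:
    return log.read_by(pmid)


def parse_annotation_store(source: Union[str, Path, bytes]) -> dict[int, set[tuple[str, str]]]:
    """Tab-delimited (pmid, aspect, concept_id) rows into a mapping."""
    if isinstance(source, bytes):
        text = source.decode()
    elif isinstance(source, Path) or (isinstance(source, str)
                                      and "\n" not in source
                                      and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = source
    store: dict[int, set[tuple[str, str]]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        pmid_s, aspect, concept_id = line.split("\t")
        store.setdefault(int(pmid_s), set()).add((aspect, concept_id))
    return store


def decorate_results(results: Iterable,
                     annotation_store: Mapping[int, set[tuple[str, str]]],
                     log: CurationLog) -> list[ResultDecoration]:
    """Triage indicators for each result.

    ``results`` may be RankedResult objects or bare PMIDs. Aspects come
    only from the annotation store; read-by only from the log.
    """
    decorations = []
    for result in results:
        pmid = result if isinstance(result, int) else result.pmid
        annotations = annotation_store.get(pmid, set())
        decorations.append(ResultDecoration(
            pmid=pmid,
            in_database=pmid in annotation_store,
            aspects={aspect for aspect, _ in annotations},
            read_by=log.read_by(pmid),
        ))
    return decorations


def import_article(log: CurationLog,
                   annotation_store: dict[int, set[tuple[str, str]]],
                   pmid: int, curator: str, timestamp: int) -> None:
    """Model the bucket-icon import: log the event and register the
    reference locally (no aspects until terms are added)."""
    log.log_event(CurationEvent("import", pmid, curator, timestamp))
    annotation_store.setdefault(pmid, set())
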