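"""MEDLINE/PubMed citation parsing and the versioned article store.

Citations arrive as PubMed article-set XML (NLM DTD:
``PubmedArticleSet/PubmedArticle/MedlineCitation``). Parsed records are
held in a single-node, file-backed key-value store whose keys are the
zero-padded, character-reversed PMID — the reversal spreads sequential
PMIDs across the keyspace, emulating the load-balancing key scheme of a
distributed column store. Every write carries a timestamp and the store
retains the ``max_versions`` most recent versions per key, so nightly
re-runs never have to delete stale payloads: the newest timestamp wins
on read.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Union

from lxml import etree

logger = logging.getLogger("conceptlit.medline")

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}

DEFAULT_MAX_VERSIONS = 3


class MedlineParseError(ValueError):
    """Malformed PubMed article-set XML."""


class StoreIntegrityError(RuntimeError):
    """A stored payload failed to deserialize."""


@dataclass(frozen=True)
class PubDate:
    year: int
    month: int | None = None
    day: int | None = None


@dataclass
class ArticleRecord:
    """One PubMed citation: the fields the tagger and index consume."""

    pmid: int
    title: str
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    pub_date: PubDate = field(default_factory=lambda: PubDate(1900))
    journal: str = ""

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")
        if not (1800 <= self.pub_date.year <= 2100):
            raise ValueError(f"pub_date year out of range: {self.pub_date.year}")


@dataclass
class UpdateStats:
    """Partition of a write batch: every record seen is new, replaced or stale."""

    n_seen: int = 0
    n_new: int = 0
    n_replaced: int = 0
    n_ignored_stale: int = 0

    def __add__(self, other: "UpdateStats") -> "UpdateStats":
        return UpdateStats(
            self.n_seen + other.n_seen,
            self.n_new + other.n_new,
            self.n_replaced + other.n_replaced,
            self.n_ignored_stale + other.n_ignored_stale,
        )


# ---------------------------------------------------------------------------
# XML parsing and serialization
# ---------------------------------------------------------------------------

def _text(elem, path: str, default: str = "") -> str:
    found = elem.find(path)
    if found is None:
        return default
    return "".join(found.itertext())


def _parse_pub_date(citation) -> PubDate:
    date_elem = citation.find(".//Article/Journal/JournalIssue/PubDate")
    if date_elem is None:
        date_elem = citation.find(".//DateCompleted")
    year, month, day = 1900, None, None
    if date_elem is not None:
        y = _text(date_elem, "Year")
        if y.isdigit():
            year = int(y)
        m = _text(date_elem, "Month")
        if m.isdigit():
            month = int(m)
        elif m[:3].lower() in _MONTHS:
            month = _MONTHS[m[:3].lower()]
        d = _text(date_elem, "Day")
        if d.isdigit():
            day = int(d)
    return PubDate(year, month, day)


def _record_from_citation(citation) -> ArticleRecord | None:
    pmid_text = _text(citation, "PMID")
    if not pmid_text.isdigit():
        logger.warning("citation without PMID skipped")
        return None
    title = _text(citation, ".//Article/ArticleTitle").strip()
    if not title:
        logger.warning("citation %s has no title; rejected", pmid_text)
        return None
    abstract_parts = [
        "".join(t.itertext())
        for t in citation.findall(".//Article/Abstract/AbstractText")
    ]
    mesh = [
        "".join(d.itertext())
        for d in citation.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
    ]
    return ArticleRecord(
        pmid=int(pmid_text),
        title=title,
        abstract=" ".join(p for p in abstract_parts if p).strip(),
        mesh_terms=mesh,
        pub_date=_parse_pub_date(citation),
        journal=_text(citation, ".//Article/Journal/Title").strip(),
    )


def parse_medline_xml(source: Union[bytes, str, Path, BinaryIO]) -> list[ArticleRecord]:
    """Parse a PubMed article set into :class:`ArticleRecord` objects.

    ``source`` may be XML bytes, a path, or an open binary stream. Records
    come back in document order; a citation lacking an abstract yields
    ``abstract=""``; citations without a PMID or title are skipped with a
    warning. Malformed XML raises :class:`MedlineParseError` naming the
    approximate byte offset of the fault.
    """
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        offset = 0
        if exc.lineno and exc.lineno > 0:
            lines = data.split(b"\n")
            offset = sum(len(l) + 1 for l in lines[: exc.lineno - 1])
            offset += max(exc.offset or 0, 0)
        raise MedlineParseError(
            f"malformed MEDLINE XML near byte offset {offset}: {exc.msg}"
        ) from exc

    records: list[ArticleRecord] = []
    seen: set[int] = set()
    for citation in root.iter("MedlineCitation"):
        record = _record_from_citation(citation)
        if record is None:
            continue
        if record.pmid in seen:
            logger.warning("duplicate PMID %d in batch; keeping first", record.pmid)
            continue
        seen.add(record.pmid)
        records.append(record)
    return records


def record_to_xml(record: ArticleRecord) -> str:
    """Serialize one record as a ``PubmedArticle`` element (payload format)."""
    art = etree.Element("PubmedArticle")
    cit = etree.SubElement(art, "MedlineCitation")
    etree.SubElement(cit, "PMID").text = str(record.pmid)
    article = etree.SubElement(cit, "Article")
    journal = etree.SubElement(article, "Journal")
    etree.SubElement(journal, "Title").text = record.journal
    issue = etree.SubElement(journal, "JournalIssue")
    pd = etree.SubElement(issue, "PubDate")
    etree.SubElement(pd, "Year").text = str(record.pub_date.year)
    if record.pub_date.month is not None:
        etree.SubElement(pd, "Month").text = str(record.pub_date.month)
    if record.pub_date.day is not None:
        etree.SubElement(pd, "Day").text = str(record.pub_date.day)
    etree.SubElement(article, "ArticleTitle").text = record.title
    if record.abstract:
        abstract = etree.SubElement(article, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = record.abstract
    if record.mesh_terms:
        mhl = etree.SubElement(cit, "MeshHeadingList")
        for term in record.mesh_terms:
            mh = etree.SubElement(mhl, "MeshHeading")
            etree.SubElement(mh, "DescriptorName").text = term
    return etree.tostring(art, encoding="unicode")


def records_to_xml(records: Iterable[ArticleRecord]) -> str:
    """Serialize records as a full PubMed article set document."""
    root = etree.Element("PubmedArticleSet")
    for record in records:
        root.append(etree.fromstring(record_to_xml(record)))
    return etree.tostring(root, encoding="unicode", pretty_print=True)


# ---------------------------------------------------------------------------
# Versioned key-value store
# ---------------------------------------------------------------------------

def make_store_key(pmid: int) -> str:
    """Reversed, zero-padded PMID: the store's load-balancing key.

    PMIDs are zero-padded to 9 digits before reversal so keys have uniform
    length and the scheme is injective for any PMID below 10^9.
    """
    if pmid <= 0:
        raise ValueError(f"pmid must be positive, got {pmid}")
    return str(pmid).zfill(9)[::-1]


def pmid_from_store_key(key: str) -> int:
    return int(key[::-1])


class ArticleStore:
    """Versioned article store over a single sqlite3 file.

    Each (key, timestamp) cell holds one serialized article. Writes keep
    the ``max_versions`` largest timestamps per key regardless of arrival
    order; reads return the payload with the maximum timestamp.
    """

    def __init__(self, path: Union[str, Path] = ":memory:",
                 max_versions: int = DEFAULT_MAX_VERSIONS):
        if max_versions < 1:
            raise ValueError("max_versions must be >= 1")
        self.max_versions = max_versions
        self._conn = sqlite3.connect(str(path))
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS cells ("
            " key TEXT NOT NULL, ts INTEGER NOT NULL, payload TEXT NOT NULL,"
            " PRIMARY KEY (key, ts))"
        )

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "ArticleStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- write path ---------------------------------------------------------

    def put_article(self, record: ArticleRecord, timestamp: int) -> UpdateStats:
        """Write one timestamped version; returns a one-record stats delta."""
        key = make_store_key(record.pmid)
        cur = self._conn.execute("SELECT MAX(ts) FROM cells WHERE key = ?", (key,))
        prev_max = cur.fetchone()[0]
        self._conn.execute(
            "INSERT OR REPLACE INTO cells (key, ts, payload) VALUES (?, ?, ?)",
            (key, timestamp, record_to_xml(record)),
        )
        # Retention: drop everything but the max_versions newest timestamps.
        self._conn.execute(
            "DELETE FROM cells WHERE key = ? AND ts NOT IN ("
            " SELECT ts FROM cells WHERE key = ? ORDER BY ts DESC LIMIT ?)",
            (key, key, self.max_versions),
        )
        self._conn.commit()
        if prev_max is None:
            return UpdateStats(n_seen=1, n_new=1)
        if timestamp > prev_max:
            return UpdateStats(n_seen=1, n_replaced=1)
        return UpdateStats(n_seen=1, n_ignored_stale=1)

    def incremental_update(self, records: Iterable[ArticleRecord],
                           timestamp: int) -> UpdateStats:
        """Apply a nightly-style batch under one shared timestamp."""
        stats = UpdateStats()
        for record in records:
            stats = stats + self.put_article(record, timestamp)
        return stats

    # -- read path ----------------------------------------------------------

    def get_article(self, pmid: int) -> ArticleRecord | None:
        """Latest version of the article, or None if never written."""
        key = make_store_key(pmid)
        cur = self._conn.execute(
            "SELECT payload FROM cells WHERE key = ? ORDER BY ts DESC LIMIT 1",
            (key,),
        )
        row = cur.fetchone()
        if row is None:
            return None
        try:
            records = parse_medline_xml(
                b"<PubmedArticleSet>" + row[0].encode() + b"</PubmedArticleSet>"
            )
            if len(records) != 1:
                raise ValueError("payload did not yield one record")
        except (MedlineParseError, ValueError) as exc:
            raise StoreIntegrityError(f"corrupt payload for key {key!r}") from exc
        return records[0]

    def versions(self, pmid: int) -> list[tuple[int, str]]:
        """All retained (timestamp, payload) pairs, newest first."""
        cur = self._conn.execute(
            "SELECT ts, payload FROM cells WHERE key = ? ORDER BY ts DESC",
            (make_store_key(pmid),),
        )
        return [(ts, payload) for ts, payload in cur.fetchall()]

    def pmids(self) -> list[int]:
        cur = self._conn.execute("SELECT key FROM cells GROUP BY key")
        return sorted(pmid_from_store_key(k) for (k,) in cur.fetchall())

    def __len__(self) -> int:
        return len(self.pmids())
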