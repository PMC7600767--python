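"""Reading, validating and tokenizing timestamped document collections.

A corpus is an ordered list of :class:`Document` records (id, year, title,
abstract, language tag) with derived per-year totals.  Three dialects are
read: JSON lines, TSV with a header row, and a MEDLINE-style XML subset
(PMID / ArticleTitle / AbstractText / PubDate).

Tokenization is deliberately simple and fully specified: Unicode NFC,
lowercase, ASCII punctuation stripped except intra-word hyphens; a
hyphenated compound is emitted once joined and once per part, so both
"non-small-cell" and "cell" are visible to downstream window statistics.
"""

from __future__ import annotations

import csv
import io
import json
import re
import unicodedata
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Document",
    "Corpus",
    "CorpusFormatError",
    "RecordError",
    "load_corpus",
    "save_corpus_jsonl",
    "tokenize",
]

#: Calendar-year window a document must fall in to be considered dated.
DEFAULT_YEAR_RANGE = (1900, 2100)

FORMATS = ("jsonl", "tsv", "medline_xml")


class CorpusFormatError(ValueError):
    """Unknown dialect name or a structurally unreadable file."""


class RecordError(ValueError):
    """A single record failed validation; carries its position."""

    def __init__(self, position: int | str, message: str):
        self.position = position
        super().__init__(f"record {position}: {message}")


@dataclass(frozen=True)
class Document:
    """One timestamped text record.

    ``year`` is a calendar year; records whose year falls outside the
    configured window are retained but ``in_range`` is False so statistics
    can exclude them explicitly.
    """

    doc_id: str
    year: int
    title: str = ""
    abstract: str = ""
    language: str = "en"

    def __post_init__(self) -> None:
        if not (self.title or self.abstract):
            raise ValueError(f"document {self.doc_id!r}: title and abstract both empty")
        if not self.language:
            raise ValueError(f"document {self.doc_id!r}: empty language tag")

    def in_range(self, year_range: tuple[int, int] = DEFAULT_YEAR_RANGE) -> bool:
        lo, hi = year_range
        return lo <= self.year <= hi

    def fields(self) -> tuple[str, str]:
        """Title and abstract as distinct text units (windows never cross)."""
        return (self.title, self.abstract)


@dataclass
class Corpus:
    """Ordered document collection with derived per-year totals."""

    documents: list[Document] = field(default_factory=list)

    @property
    def year_totals(self) -> dict[int, int]:
        totals: dict[int, int] = {}
        for doc in self.documents:
            totals[doc.year] = totals.get(doc.year, 0) + 1
        return totals

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.documents == other.documents


_JSONL_KEYS = ("doc_id", "year", "title", "abstract", "language")


def _coerce_year(raw: object, position: int | str) -> int:
    if isinstance(raw, bool) or raw is None:
        raise RecordError(position, f"missing or unparseable year: {raw!r}")
    if isinstance(raw, int):
        return raw
    m = re.search(r"(\d{4})", str(raw))
    if m is None:
        raise RecordError(position, f"missing or unparseable year: {raw!r}")
    return int(m.group(1))


def _doc_from_mapping(rec: dict, position: int | str) -> Document:
    year = _coerce_year(rec.get("year"), position)
    try:
        return Document(
            doc_id=str(rec.get("doc_id", position)),
            year=year,
            title=str(rec.get("title") or ""),
            abstract=str(rec.get("abstract") or ""),
            language=str(rec.get("language") or "en"),
        )
    except ValueError as exc:
        raise RecordError(position, str(exc)) from exc


def _iter_jsonl(path: Path) -> Iterator[Document]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordError(lineno, f"invalid JSON: {exc}") from exc
            yield _doc_from_mapping(rec, lineno)


def _iter_tsv(path: Path) -> Iterator[Document]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, rec in enumerate(reader, start=2):
            yield _doc_from_mapping(rec, lineno)


def _iter_medline_xml(path: Path) -> Iterator[Document]:
    # Subset of the MEDLINE citation schema: PMID, ArticleTitle,
    # AbstractText, PubDate.  Year = first 4-digit run inside PubDate,
    # tolerating dialects like <MedlineDate>2007 Jan-Feb</MedlineDate>.
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise CorpusFormatError(f"{path}: not well-formed XML: {exc}") from exc
    articles = tree.getroot().iter("PubmedArticle")
    found = False
    for idx, art in enumerate(articles, start=1):
        found = True
        pmid = art.findtext(".//PMID") or str(idx)
        title = art.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (el.text or "") for el in art.iter("AbstractText")
        ).strip()
        pubdate = art.find(".//PubDate")
        raw_year = "".join(pubdate.itertext()) if pubdate is not None else None
        year = _coerce_year(raw_year, f"PMID {pmid}")
        lang = art.findtext(".//Language") or "en"
        try:
            yield Document(pmid, year, title, abstract, lang.lower())
        except ValueError as exc:
            raise RecordError(f"PMID {pmid}", str(exc)) from exc
    if not found and tree.getroot().tag not in ("PubmedArticleSet",):
        raise CorpusFormatError(f"{path}: no PubmedArticle elements found")


def load_corpus(path: str | Path, format_id: str = "jsonl") -> Corpus:
    """Read a corpus file in the named dialect.

    Parameters
    ----------
    path:
        File to read.  An empty file yields an empty corpus.
    format_id:
        One of ``jsonl``, ``tsv``, ``medline_xml``.

    Raises
    ------
    CorpusFormatError
        Unknown ``format_id`` or structurally unreadable file.
    RecordError
        A record is invalid (e.g. no parseable year); the error names the
        line / record so nothing is dropped silently.
    """
    path = Path(path)
    if format_id not in FORMATS:
        raise CorpusFormatError(
            f"unknown format {format_id!r}; expected one of {FORMATS}"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return Corpus()
    readers = {
        "jsonl": _iter_jsonl,
        "tsv": _iter_tsv,
        "medline_xml": _iter_medline_xml,
    }
    return Corpus(documents=list(readers[format_id](path)))


def save_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Serialize to the JSONL dialect; round-trips through load_corpus."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            rec = {
                "doc_id": doc.doc_id,
                "year": doc.year,
                "title": doc.title,
                "abstract": doc.abstract,
                "language": doc.language,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# Word = letters/digits possibly joined by single internal hyphens.
_WORD_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def tokenize(text: str, language: str = "en", expand_hyphens: bool = True) -> list[str]:
    """Normalize text to a deterministic lowercase token sequence.

    Unicode NFC, casefolded via ``str.lower``, punctuation outside words
    dropped.  A hyphenated compound is kept joined AND split: the joined
    form is emitted first, immediately followed by its parts, so window
    statistics see both granularities.  Empty text gives an empty list.
    """
    if not text:
        return []
    text = unicodedata.normalize("NFC", text).lower()
    tokens: list[str] = []
    for match in _WORD_RE.finditer(text):
        word = match.group(0)
        tokens.append(word)
        if expand_hyphens and "-" in word:
            tokens.extend(p for p in word.split("-") if p)
    return tokens
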