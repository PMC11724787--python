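"""Corpus I/O: article models, JATS-style XML, abstract records, expression tables.

Articles come from two source kinds mirroring how open-access biomedical full
text is distributed: JATS-style XML (one article per file, titled ``<sec>``
divisions under ``<body>``) and plain tagged abstract records of the kind
returned by PubMed's EFetch in MEDLINE format.  Parsing is deliberately
lenient — corpora of millions of heterogeneous files must never die on one
malformed article — so a file-level problem is logged and the article skipped
by the caller, never raised mid-stream.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional

from lxml import etree

logger = logging.getLogger(__name__)

#: Sentinel journal string when front matter carries no journal title.
UNKNOWN_JOURNAL = "unknown"


class SourceKind(str, Enum):
    fulltext_xml = "fulltext_xml"
    abstract_record = "abstract_record"
    synthetic = "synthetic"


@dataclass
class Section:
    title: str
    text: str


@dataclass
class Article:
    """One document: identifier, journal/year metadata, ordered titled sections."""

    article_id: str
    journal: str
    year: Optional[int]  # None = unknown
    source_kind: SourceKind
    sections: List[Section] = field(default_factory=list)


class ParseError(ValueError):
    """Raised when an article file cannot be parsed at all."""


# ---------------------------------------------------------------------------
# JATS-style full-text XML
# ---------------------------------------------------------------------------

def _element_text(elem) -> str:
    """All text under ``elem`` excluding nested <sec> divisions."""
    parts = []
    if elem.text:
        parts.append(elem.text)
    for child in elem:
        tag = etree.QName(child).localname if isinstance(child.tag, str) else ""
        if tag not in {"sec", "title"}:
            parts.append(_element_text(child))
        if child.tail:
            parts.append(child.tail)
    return "".join(parts)


def _find_year(front) -> Optional[int]:
    """Publication year: electronic date preferred, then print, then any."""
    if front is None:
        return None
    dates = front.findall(".//pub-date")
    def year_of(d):
        y = d.findtext("year")
        try:
            return int(y) if y else None
        except ValueError:
            return None
    for want in ("epub", "ppub"):
        for d in dates:
            if want in (d.get("pub-type", ""), d.get("date-type", "")):
                y = year_of(d)
                if y is not None:
                    return y
    for d in dates:
        y = year_of(d)
        if y is not None:
            return y
    return None


def parse_fulltext_xml(xml_text: str, *, source_name: str = "<string>") -> Article:
    """Parse one JATS-style XML article into an :class:`Article`.

    One :class:`Section` is produced per ``<sec>`` division, flattened in
    document order with titles preserved (a nested subsection becomes its own
    section after its parent).  A front-matter ``<abstract>`` is included as a
    section titled "Abstract".  Missing ``<body>`` yields an article with no
    sections and a logged warning; the caller filters such articles out.
    """
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML in {source_name}: {exc}") from exc

    front = root.find(".//front")
    journal = None
    if front is not None:
        journal = front.findtext(".//journal-title")
    article_id = root.findtext(".//article-id") or source_name
    year = _find_year(front)

    sections: List[Section] = []
    abstract = root.find(".//front//abstract")
    if abstract is not None:
        text = _element_text(abstract).strip()
        if text:
            sections.append(Section(title="Abstract", text=text))

    body = root.find(".//body")
    if body is None:
        logger.warning("article %s has no <body>; emitting empty section list",
                       article_id)
    else:
        for sec in body.iter("sec"):
            title = (sec.findtext("title") or "").strip()
            text = _element_text(sec).strip()
            if text or title:
                sections.append(Section(title=title, text=text))
        if not sections:
            # body with bare paragraphs and no <sec> divisions
            text = _element_text(body).strip()
            if text:
                sections.append(Section(title="", text=text))

    return Article(
        article_id=article_id,
        journal=journal.strip() if journal else UNKNOWN_JOURNAL,
        year=year,
        source_kind=SourceKind.fulltext_xml,
        sections=sections,
    )


def article_to_jats(article: Article) -> str:
    """Serialize an :class:`Article` as a minimal JATS-style XML document.

    Inverse (up to whitespace) of :func:`parse_fulltext_xml`; used by the
    synthetic corpus generator so the XML reader is exercised end to end.
    """
    root = etree.Element("article")
    front = etree.SubElement(root, "front")
    jm = etree.SubElement(front, "journal-meta")
    jt = etree.SubElement(jm, "journal-title")
    jt.text = article.journal
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id")
    aid.text = article.article_id
    if article.year is not None:
        pd = etree.SubElement(am, "pub-date", {"pub-type": "epub"})
        y = etree.SubElement(pd, "year")
        y.text = str(article.year)
    body = etree.SubElement(root, "body")
    for section in article.sections:
        if section.title == "Abstract":
            abstract = etree.SubElement(am, "abstract")
            p = etree.SubElement(abstract, "p")
            p.text = section.text
            continue
        sec = etree.SubElement(body, "sec")
        title = etree.SubElement(sec, "title")
        title.text = section.title
        p = etree.SubElement(sec, "p")
        p.text = section.text
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Abstract records (MEDLINE-style tagged fields)
# ---------------------------------------------------------------------------

_FIELD_TAGS = {"PMID", "JT", "DP", "AB"}


def parse_abstract_record(record: str) -> Optional[Article]:
    """Parse one tagged abstract record into an Article with one section.

    Expected tags: ``PMID-`` identifier, ``JT  -`` journal title, ``DP  -``
    publication date (year is the first 4-digit prefix), ``AB  -`` abstract
    text (continuation lines are indented).  A record without abstract text
    is skipped (returns None) with a logged warning.
    """
    fields: dict[str, str] = {}
    current: Optional[str] = None
    for line in record.splitlines():
        if not line.strip():
            continue
        tag = line[:4].strip().rstrip("-").strip()
        if len(line) > 5 and line[4] == "-" and tag in _FIELD_TAGS:
            current = tag
            fields[current] = line[6:].strip()
        elif current and line.startswith(" "):
            fields[current] += " " + line.strip()
    abstract = fields.get("AB", "").strip()
    pmid = fields.get("PMID", "").strip()
    if not abstract:
        logger.warning("abstract record %s has no abstract text; skipped",
                       pmid or "<no id>")
        return None
    year: Optional[int] = None
    dp = fields.get("DP", "")
    if len(dp) >= 4 and dp[:4].isdigit():
        year = int(dp[:4])
    return Article(
        article_id=pmid or f"record:{hash(record) & 0xFFFFFFF:x}",
        journal=fields.get("JT", UNKNOWN_JOURNAL).strip() or UNKNOWN_JOURNAL,
        year=year,
        source_kind=SourceKind.abstract_record,
        sections=[Section(title="Abstract", text=abstract)],
    )


def parse_abstract_file(text: str) -> List[Article]:
    """Split a file of blank-line-separated records and parse each one."""
    out = []
    for chunk in text.split("\n\n"):
        if not chunk.strip():
            continue
        article = parse_abstract_record(chunk)
        if article is not None:
            out.append(article)
    return out


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    """One extracted predicate expression with full provenance."""

    expression_text: str
    organ: str
    subject_adjective: Optional[str]
    sentence_text: str
    article_id: str
    journal: str
    year: Optional[int]
    section_title: str


_COLUMNS = [
    "expression_text",
    "organ",
    "subject_adjective",
    "sentence_text",
    "article_id",
    "journal",
    "year",
    "section_title",
]


def write_expressions(records: Iterable[ExpressionRecord], path: Path | str) -> None:
    """Write records as UTF-8 tab-separated values with a header row."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_COLUMNS)
            for r in records:
                writer.writerow([
                    r.expression_text,
                    r.organ,
                    r.subject_adjective if r.subject_adjective is not None else "",
                    r.sentence_text,
                    r.article_id,
                    r.journal,
                    r.year if r.year is not None else "",
                    r.section_title,
                ])
    except OSError as exc:
        raise OSError(f"cannot write expression table to {path}: {exc}") from exc


def read_expressions(path: Path | str) -> List[ExpressionRecord]:
    """Read a TSV expression table; inverse of :func:`write_expressions`."""
    path = Path(path)
    out: List[ExpressionRecord] = []
    try:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header != _COLUMNS:
                raise ParseError(f"{path}: unexpected header {header!r}")
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(_COLUMNS):
                    raise ParseError(
                        f"{path} line {lineno}: expected {len(_COLUMNS)} fields, "
                        f"got {len(row)}"
                    )
                out.append(ExpressionRecord(
                    expression_text=row[0],
                    organ=row[1],
                    subject_adjective=row[2] or None,
                    sentence_text=row[3],
                    article_id=row[4],
                    journal=row[5],
                    year=int(row[6]) if row[6] else None,
                    section_title=row[7],
                ))
    except OSError as exc:
        raise OSError(f"cannot read expression table from {path}: {exc}") from exc
    return out


def write_expressions_jsonl(records: Iterable[ExpressionRecord],
                            path: Path | str) -> None:
    """JSON-lines alternative for nested/downstream tooling."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.__dict__, ensure_ascii=False) + "\n")


def read_expressions_jsonl(path: Path | str) -> List[ExpressionRecord]:
    path = Path(path)
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(ExpressionRecord(**json.loads(line)))
            except (json.JSONDecodeError, TypeError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return out
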