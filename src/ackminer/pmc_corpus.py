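"""Harvest acknowledgement sections from JATS/PMC XML.

Full-text open-access depositions are large; building a DOM for a million
articles just to read one section is wasteful.  This module therefore locates
the acknowledgement section with a shallow, linear regular-expression scan:
the JATS ``<ack>`` element when present, otherwise a legacy
"Acknowledg(e)ments" heading followed by paragraph text.  Only the matched
region is ever tag-stripped.
"""

from __future__ import annotations

import html
import json
import logging
import re
import tarfile
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "ArticleRecord",
    "Acknowledgement",
    "MalformedAckError",
    "CorpusStats",
    "parse_acknowledgement",
    "keyword_filter",
    "stream_corpus",
    "write_jsonl",
    "read_jsonl",
]


class MalformedAckError(ValueError):
    """An acknowledgement region opens but never closes."""


@dataclass(frozen=True)
class ArticleRecord:
    """Identity and provenance of one article."""

    article_id: str
    journal: Optional[str] = None
    year: Optional[int] = None
    raw_xml: str = ""

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")
        if self.year is not None and not (1000 <= self.year <= 9999):
            raise ValueError(f"year must be a 4-digit integer, got {self.year}")


@dataclass(frozen=True)
class Acknowledgement:
    """The plain-text acknowledgement paragraph of one article."""

    article: ArticleRecord
    text: str
    char_offsets: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("acknowledgement text must be non-empty")
        if self.char_offsets is not None:
            start, end = self.char_offsets
            sliced = strip_markup(self.article.raw_xml[start:end])
            if sliced != self.text:
                raise ValueError(
                    "char_offsets slice does not reproduce text after "
                    "tag stripping"
                )


_ACK_OPEN_RE = re.compile(r"<ack(?:\s[^>]*)?>", re.IGNORECASE)
_ACK_CLOSE_RE = re.compile(r"</ack\s*>", re.IGNORECASE)
# Legacy fallback: a heading, optionally wrapped in title/bold markup, then
# everything up to the next section-like element.
_HEADING_RE = re.compile(
    r"Acknowledge?ments?\s*[:.]?\s*(?:</(?:title|bold|b|h[1-6])\s*>)?",
    re.IGNORECASE,
)
_NEXT_SECTION_RE = re.compile(
    r"<(?:title|sec|ref-list|back|h[1-6])\b|</(?:sec|back|body|article)\s*>",
    re.IGNORECASE,
)
_TAG_RE = re.compile(r"<[^>]*>")
# word-boundary match: hyphen compounds ("antibody-producing") count,
# run-on coinages ("antibodylike", "autoantibody") do not
_KEYWORD_RE = re.compile(r"(?<!\w)antibod(?:y|ies)(?!\w)", re.IGNORECASE)


def strip_markup(fragment: str) -> str:
    """Drop tags, unescape entities, NFC-normalize, collapse whitespace."""
    text = _TAG_RE.sub(" ", fragment)
    text = html.unescape(text)
    text = unicodedata.normalize("NFC", text)
    return " ".join(text.split())


def _first_group(pattern: str, xml: str) -> Optional[str]:
    m = re.search(pattern, xml, re.IGNORECASE | re.DOTALL)
    return m.group(1).strip() if m else None


def parse_article_record(xml: str, fallback_id: str = "") -> ArticleRecord:
    """Pull id/journal/year out of a JATS document with shallow regexes."""
    article_id = _first_group(
        r'<article-id[^>]*pub-id-type="pmc[^"]*"[^>]*>\s*([^<]+?)\s*</article-id>',
        xml,
    ) or _first_group(r"<article-id[^>]*>\s*([^<]+?)\s*</article-id>", xml)
    journal = _first_group(r"<journal-title[^>]*>(.*?)</journal-title>", xml)
    if journal is not None:
        journal = strip_markup(journal)
    year_text = _first_group(r"<pub-date[^>]*>.*?<year[^>]*>\s*(\d{4})\s*</year>", xml)
    year = int(year_text) if year_text else None
    return ArticleRecord(
        article_id=article_id or fallback_id or "unknown",
        journal=journal,
        year=year,
        raw_xml=xml,
    )


def parse_acknowledgement(
    document: str, article: Optional[ArticleRecord] = None
) -> Optional[Acknowledgement]:
    """Extract the acknowledgement paragraph from a JATS-XML string.

    Returns ``None`` when the document has no acknowledgement section.
    Raises :class:`MalformedAckError` when an ``<ack>`` element opens but
    never closes; all other malformations simply yield ``None``.
    """
    if article is None:
        article = parse_article_record(document, fallback_id="unknown")

    open_m = _ACK_OPEN_RE.search(document)
    if open_m is not None:
        close_m = _ACK_CLOSE_RE.search(document, open_m.end())
        if close_m is None:
            raise MalformedAckError("<ack> opened but never closed")
        start, end = open_m.end(), close_m.start()
        text = strip_markup(document[start:end])
        if not text:
            return None
        return Acknowledgement(article=article, text=text, char_offsets=(start, end))

    head_m = _HEADING_RE.search(document)
    if head_m is None:
        return None
    start = head_m.end()
    next_m = _NEXT_SECTION_RE.search(document, start)
    end = next_m.start() if next_m else len(document)
    text = strip_markup(document[start:end])
    if not text:
        return None
    return Acknowledgement(article=article, text=text, char_offsets=(start, end))


def keyword_filter(ack: Union[Acknowledgement, str]) -> bool:
    """True iff the text mentions "antibody" or "antibodies" as a whole word.

    Matching is case-insensitive on NFC-normalized text.  Hyphen compounds
    such as "antibody-producing" count; run-on coinages ("antibodylike")
    do not.
    """
    text = ack.text if isinstance(ack, Acknowledgement) else ack
    return _KEYWORD_RE.search(unicodedata.normalize("NFC", text)) is not None


@dataclass
class CorpusStats:
    """Mutable tally filled in by :func:`stream_corpus`."""

    documents: int = 0
    with_acknowledgement: int = 0
    keyword_hits: int = 0
    skipped: int = 0


def _iter_source_documents(source: Union[str, Path]) -> Iterator[tuple[str, str]]:
    """Yield (name, xml-text) in lexicographic name order."""
    source = Path(source)
    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in (".xml", ".nxml")
        )
        for path in paths:
            yield path.name, path.read_text("utf-8")
    elif source.name.endswith((".tar.gz", ".tgz", ".tar")):
        with tarfile.open(source) as tar:
            members = sorted(
                (m for m in tar.getmembers() if m.isfile()
                 and m.name.lower().endswith((".xml", ".nxml"))),
                key=lambda m: m.name,
            )
            for member in members:
                fh = tar.extractfile(member)
                if fh is None:
                    continue
                yield member.name, fh.read().decode("utf-8")
    else:
        yield source.name, source.read_text("utf-8")


def stream_corpus(
    source: Union[str, Path], stats: Optional[CorpusStats] = None
) -> Iterator[Acknowledgement]:
    """Yield keyword-positive acknowledgements from a directory or archive.

    Files are visited in lexicographic name order; unreadable or malformed
    files are logged and counted in ``stats.skipped``, never raised.
    """
    if stats is None:
        stats = CorpusStats()
    for name, xml in _iter_source_documents(source):
        stats.documents += 1
        try:
            article = parse_article_record(xml, fallback_id=Path(name).stem)
            ack = parse_acknowledgement(xml, article=article)
        except (MalformedAckError, ValueError, UnicodeDecodeError) as exc:
            stats.skipped += 1
            logger.warning("skipping %s: %s", name, exc)
            continue
        if ack is None:
            continue
        stats.with_acknowledgement += 1
        if keyword_filter(ack):
            stats.keyword_hits += 1
            yield ack
    if stats.skipped:
        logger.info("stream_corpus skipped %d unreadable document(s)", stats.skipped)


def write_jsonl(acks: Iterator[Acknowledgement], path: Union[str, Path]) -> int:
    """Write one JSON object per acknowledgement; returns the count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for ack in acks:
            fh.write(
                json.dumps(
                    {
                        "article_id": ack.article.article_id,
                        "journal": ack.article.journal,
                        "year": ack.article.year,
                        "text": ack.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def read_jsonl(path: Union[str, Path]) -> list[Acknowledgement]:
    out: list[Acknowledgement] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            article = ArticleRecord(
                article_id=rec["article_id"],
                journal=rec.get("journal"),
                year=rec.get("year"),
            )
            out.append(Acknowledgement(article=article, text=rec["text"]))
    return out
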