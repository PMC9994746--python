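"""MEDLINE/PubMed citation-dialect XML ingestion.

Extracts PMID, DOI, title, abstract, publication date, authors, language
codes and publication types from ``<PubmedArticle>`` citations; applies
date canonicalization plus the language / publication-type exclusion
filters.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import IO, Iterable

from .records import AuthorName, PaperRecord

logger = logging.getLogger(__name__)

#: Publication types excluded from the corpus: these citation kinds are
#: not plausibly the published version of a preprint (or are preprints).
EXCLUDED_PUBLICATION_TYPES = frozenset(
    {"Comment", "Published Erratum", "Review", "Preprint"}
)

_MONTH_NAMES = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}

#: Season → month-within-the-labeled-year table (NLM convention:
#: Winter issues are dated to January of the stated year).
SEASON_MONTHS = {"winter": 1, "spring": 4, "summer": 7, "fall": 10, "autumn": 10}

_YEAR_RE = re.compile(r"\b(\d{4})\b")
_DAY_RE = re.compile(r"\b(\d{1,2})\b")


class PubDateError(ValueError):
    """Raised when a publication-date string carries no parsable year."""


def canonicalize_pubdate(raw: str) -> _dt.date:
    """Canonicalize a free-text publication date to a calendar date.

    Missing day defaults to the first of the month; missing month
    defaults to January. Month names, numeric months and season strings
    are accepted. A string with no 4-digit year raises ``PubDateError``.
    """
    if not raw or not raw.strip():
        raise PubDateError("empty publication date string")
    text = raw.strip()
    ymatch = _YEAR_RE.search(text)
    if ymatch is None:
        raise PubDateError(f"no 4-digit year in publication date {raw!r}")
    year = int(ymatch.group(1))
    rest = (text[: ymatch.start()] + " " + text[ymatch.end():]).strip()

    month: int | None = None
    day: int | None = None
    tokens = re.split(r"[\s/\-,.]+", rest) if rest else []
    for tok in tokens:
        if not tok:
            continue
        low = tok.lower()
        if month is None and low[:3] in _MONTH_NAMES and not low.isdigit():
            month = _MONTH_NAMES[low[:3]]
        elif month is None and low in SEASON_MONTHS:
            month = SEASON_MONTHS[low]
        elif tok.isdigit():
            val = int(tok)
            if month is None and 1 <= val <= 12:
                month = val
            elif day is None and 1 <= val <= 31:
                day = val
    if month is None:
        month = 1
    if day is None:
        day = 1
    try:
        return _dt.date(year, month, day)
    except ValueError:
        # e.g. "Feb 30" from a damaged record: clamp to the 1st.
        return _dt.date(year, month, 1)


def author_display(name: AuthorName) -> str:
    """Single-string form: ``"<fore> <last>"`` or just ``"<last>"``."""
    return name.display()


def _text(elem: ET.Element | None) -> str | None:
    if elem is None:
        return None
    value = "".join(elem.itertext()).strip()
    return value or None


def _parse_authors(article: ET.Element) -> list[AuthorName]:
    authors: list[AuthorName] = []
    for author in article.findall(".//AuthorList/Author"):
        last = _text(author.find("LastName"))
        fore = _text(author.find("ForeName"))
        if last is None:
            collective = _text(author.find("CollectiveName"))
            logger.warning(
                "dropping author without last name (collective=%r)", collective
            )
            continue
        authors.append(AuthorName(last_name=last, fore_name=fore))
    return authors


def _parse_pubdate_element(article: ET.Element) -> str | None:
    pubdate = article.find(".//Journal/JournalIssue/PubDate")
    if pubdate is None:
        pubdate = article.find(".//PubDate")
    if pubdate is None:
        return None
    medline = _text(pubdate.find("MedlineDate"))
    if medline:
        return medline
    parts = [
        _text(pubdate.find("Year")),
        _text(pubdate.find("Season")),
        _text(pubdate.find("Month")),
        _text(pubdate.find("Day")),
    ]
    joined = " ".join(p for p in parts if p)
    return joined or None


def _parse_doi(citation: ET.Element, pubmed_article: ET.Element) -> str | None:
    for aid in pubmed_article.findall(".//ArticleIdList/ArticleId"):
        if aid.get("IdType", "").lower() == "doi":
            return _text(aid)
    for eloc in citation.findall(".//Article/ELocationID"):
        if eloc.get("EIdType", "").lower() == "doi":
            return _text(eloc)
    return None


def _parse_citation(pubmed_article: ET.Element) -> PaperRecord | None:
    citation = pubmed_article.find("MedlineCitation")
    if citation is None:
        citation = pubmed_article
    pmid = _text(citation.find("PMID"))
    if pmid is None:
        logger.warning("skipping citation without a PMID")
        return None
    article = citation.find("Article")
    if article is None:
        logger.warning("skipping PMID %s: no <Article> element", pmid)
        return None

    title = _text(article.find("ArticleTitle"))
    abstract_parts = [
        t for t in (_text(e) for e in article.findall(".//Abstract/AbstractText")) if t
    ]
    abstract = " ".join(abstract_parts) if abstract_parts else None

    raw_date = _parse_pubdate_element(article)
    if raw_date is None:
        logger.warning("excluding PMID %s: no publication date", pmid)
        return None
    try:
        pub_date = canonicalize_pubdate(raw_date)
    except PubDateError as exc:
        logger.warning("excluding PMID %s: %s", pmid, exc)
        return None

    languages = {
        lang for lang in (_text(e) for e in article.findall("Language")) if lang
    }
    pub_types = {
        pt
        for pt in (
            _text(e)
            for e in article.findall(".//PublicationTypeList/PublicationType")
        )
        if pt
    }
    return PaperRecord(
        pmid=pmid,
        doi=_parse_doi(citation, pubmed_article),
        title=title,
        abstract=abstract,
        pub_date=pub_date,
        authors=_parse_authors(article),
        language_codes=languages,
        publication_types=pub_types,
    )


def parse_pubmed_xml(source: str | Path | IO[bytes]) -> list[PaperRecord]:
    """Parse a MEDLINE-dialect XML document into ``PaperRecord`` objects.

    Citations lacking a PMID or a parsable publication date are skipped
    with a logged warning. Malformed XML raises ``ET.ParseError`` naming
    the offending position.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise ET.ParseError(f"malformed PubMed XML: {exc}") from exc
    root = tree.getroot()
    elements: Iterable[ET.Element]
    if root.tag == "PubmedArticle":
        elements = [root]
    else:
        elements = root.iter("PubmedArticle")
    records = []
    for elem in elements:
        rec = _parse_citation(elem)
        if rec is not None:
            records.append(rec)
    return records


def filter_papers(records: list[PaperRecord]) -> list[PaperRecord]:
    """Keep English-language records whose types avoid the exclusion set.

    A record passes iff its language set contains ``"eng"``, its
    publication types are disjoint from ``EXCLUDED_PUBLICATION_TYPES``,
    and it has a title (untitled records cannot be embedded).
    """
    kept = []
    for rec in records:
        if "eng" not in rec.language_codes:
            continue
        if rec.publication_types & EXCLUDED_PUBLICATION_TYPES:
            continue
        if not rec.title:
            continue
        kept.append(rec)
    return kept


def write_corpus_jsonl(records: list[PaperRecord], path: str | Path) -> None:
    """Serialize the corpus as one JSON object per line, ISO-8601 dates."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict(), ensure_ascii=False) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[PaperRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(PaperRecord.from_json_dict(json.loads(line)))
    return records
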