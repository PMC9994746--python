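"""Preprint metadata ingestion from a JSON-lines schema.

Each row carries ``doi``, ``title``, ``abstract``, ``posted_date``
(ISO-8601) and ``authors`` (either pre-split ``{fore_name, last_name}``
objects or plain display strings), plus an optional
``announced_pub_id`` naming the server-announced published version.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import IO

from .records import AuthorName, PreprintRecord

logger = logging.getLogger(__name__)

MANDATORY_FIELDS = ("doi", "title", "abstract", "posted_date", "authors")


class DuplicateDoiError(ValueError):
    def __init__(self, duplicates: list[str]):
        self.duplicates = duplicates
        super().__init__(f"duplicate preprint DOIs: {', '.join(duplicates)}")


def split_author_string(display: str) -> AuthorName:
    """Split a display name on the final whitespace token.

    ``"Mary Jane Watson"`` → fore ``"Mary Jane"``, last ``"Watson"``.
    Particles stay in the fore name; single-token names become a bare
    last name.
    """
    parts = display.strip().rsplit(None, 1)
    if len(parts) == 1:
        return AuthorName(last_name=parts[0])
    fore, last = parts
    return AuthorName(last_name=last, fore_name=fore)


def _row_to_record(row: dict) -> PreprintRecord | None:
    missing = [f for f in MANDATORY_FIELDS if row.get(f) in (None, "", [])]
    if missing:
        logger.warning(
            "skipping preprint row %r: missing %s",
            row.get("doi", "<no doi>"),
            ", ".join(missing),
        )
        return None
    authors = []
    for a in row["authors"]:
        if isinstance(a, str):
            authors.append(split_author_string(a))
        else:
            authors.append(
                AuthorName(last_name=a["last_name"], fore_name=a.get("fore_name"))
            )
    return PreprintRecord(
        doi=row["doi"],
        title=row["title"],
        abstract=row["abstract"],
        posted_date=_dt.date.fromisoformat(row["posted_date"]),
        authors=authors,
        announced_pub_id=row.get("announced_pub_id"),
    )


def parse_preprints(source: str | Path | IO[str]) -> list[PreprintRecord]:
    """Read preprint records from JSON-lines; order is preserved.

    Rows missing a mandatory field are skipped with a warning; duplicate
    DOIs raise ``DuplicateDoiError`` listing the offenders.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    records: list[PreprintRecord] = []
    seen: dict[str, int] = {}
    duplicates: list[str] = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        rec = _row_to_record(json.loads(line))
        if rec is None:
            continue
        if rec.doi in seen:
            if rec.doi not in duplicates:
                duplicates.append(rec.doi)
        seen[rec.doi] = seen.get(rec.doi, 0) + 1
        records.append(rec)
    if duplicates:
        raise DuplicateDoiError(duplicates)
    return records


def write_preprints_jsonl(records: list[PreprintRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict(), ensure_ascii=False) + "\n")
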