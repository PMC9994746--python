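"""Core record types shared across the pipeline.

Published papers and preprints are reduced to the handful of fields the
matcher actually consumes: identifiers, title/abstract text, a calendar
date, and an ordered author list.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AuthorName:
    """A single author, split into given name(s) and family name.

    ``fore_name`` is ``None`` when the source record carries no given
    name; an empty string is normalized to ``None``.
    """

    last_name: str
    fore_name: str | None = None

    def __post_init__(self) -> None:
        if not self.last_name:
            raise ValueError("AuthorName.last_name must be non-empty")
        if self.fore_name == "":
            object.__setattr__(self, "fore_name", None)

    def display(self) -> str:
        """``"<fore> <last>"`` when a fore name exists, else ``"<last>"``."""
        if self.fore_name:
            return f"{self.fore_name} {self.last_name}"
        return self.last_name


@dataclass
class PaperRecord:
    """One published article's matched-on metadata."""

    pmid: str
    title: str | None
    pub_date: _dt.date
    authors: list[AuthorName] = field(default_factory=list)
    abstract: str | None = None
    doi: str | None = None
    language_codes: set[str] = field(default_factory=set)
    publication_types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("PaperRecord.pmid must be non-empty")
        if self.authors is None:
            raise ValueError("PaperRecord.authors may be empty, never None")

    def to_json_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "doi": self.doi,
            "title": self.title,
            "abstract": self.abstract,
            "pub_date": self.pub_date.isoformat(),
            "authors": [
                {"fore_name": a.fore_name, "last_name": a.last_name}
                for a in self.authors
            ],
            "language_codes": sorted(self.language_codes),
            "publication_types": sorted(self.publication_types),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PaperRecord":
        return cls(
            pmid=d["pmid"],
            doi=d.get("doi"),
            title=d.get("title"),
            abstract=d.get("abstract"),
            pub_date=_dt.date.fromisoformat(d["pub_date"]),
            authors=[
                AuthorName(last_name=a["last_name"], fore_name=a.get("fore_name"))
                for a in d.get("authors", [])
            ],
            language_codes=set(d.get("language_codes", [])),
            publication_types=set(d.get("publication_types", [])),
        )


@dataclass
class PreprintRecord:
    """One preprint's metadata plus the optional server-announced publication."""

    doi: str
    title: str
    abstract: str
    posted_date: _dt.date
    authors: list[AuthorName] = field(default_factory=list)
    announced_pub_id: str | None = None

    def __post_init__(self) -> None:
        if not self.doi:
            raise ValueError("PreprintRecord.doi must be non-empty")

    def to_json_dict(self) -> dict:
        d = {
            "doi": self.doi,
            "title": self.title,
            "abstract": self.abstract,
            "posted_date": self.posted_date.isoformat(),
            "authors": [
                {"fore_name": a.fore_name, "last_name": a.last_name}
                for a in self.authors
            ],
        }
        if self.announced_pub_id is not None:
            d["announced_pub_id"] = self.announced_pub_id
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "PreprintRecord":
        from .preprint_ingest import split_author_string  # local, avoids cycle

        authors = []
        for a in d.get("authors", []):
            if isinstance(a, str):
                authors.append(split_author_string(a))
            else:
                authors.append(
                    AuthorName(last_name=a["last_name"], fore_name=a.get("fore_name"))
                )
        return cls(
            doi=d["doi"],
            title=d["title"],
            abstract=d["abstract"],
            posted_date=_dt.date.fromisoformat(d["posted_date"]),
            authors=authors,
            announced_pub_id=d.get("announced_pub_id"),
        )
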