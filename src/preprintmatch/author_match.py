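"""Author-set similarity: Jaccard over last names with a flip check.

Two authors count as matching when their last names match exactly after
case folding. Because first and last names are occasionally swapped on
the preprint side, the paper's last names are also compared against the
preprint's fore names, and the higher of the two Jaccard scores wins.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

from .records import AuthorName


@dataclass(frozen=True)
class AuthorFeature:
    straight_jaccard: float
    flipped_jaccard: float

    @property
    def score(self) -> float:
        return max(self.straight_jaccard, self.flipped_jaccard)


def _normalize(token: str, strip_diacritics: bool = False) -> str:
    token = token.strip().casefold()
    if strip_diacritics:
        token = "".join(
            c
            for c in unicodedata.normalize("NFKD", token)
            if not unicodedata.combining(c)
        )
    return token


def last_name_set(
    authors: list[AuthorName], strip_diacritics: bool = False
) -> set[str]:
    """Case-folded, trimmed set of last names; duplicates collapse."""
    return {
        _normalize(a.last_name, strip_diacritics)
        for a in authors
        if a.last_name.strip()
    }


def fore_name_set(
    authors: list[AuthorName], strip_diacritics: bool = False
) -> set[str]:
    """Final fore-name token of each author (the swappable name field)."""
    names = set()
    for a in authors:
        if a.fore_name and a.fore_name.strip():
            names.add(_normalize(a.fore_name.split()[-1], strip_diacritics))
    return names


def jaccard(a: set, b: set) -> float:
    """|a∩b| / |a∪b|; 0.0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def author_score(
    preprint_authors: list[AuthorName],
    paper_authors: list[AuthorName],
    strip_diacritics: bool = False,
) -> AuthorFeature:
    """Max of straight last-name Jaccard and the fore/last flip Jaccard.

    The flip check is one-directional: paper last names against preprint
    fore names (the observed failure is swapped name fields in preprint
    records, not papers).
    """
    paper_last = last_name_set(paper_authors, strip_diacritics)
    straight = jaccard(last_name_set(preprint_authors, strip_diacritics), paper_last)
    flipped = jaccard(fore_name_set(preprint_authors, strip_diacritics), paper_last)
    return AuthorFeature(straight_jaccard=straight, flipped_jaccard=flipped)
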