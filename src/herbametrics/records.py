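"""Core record containers for bibliographic corpora.

A :class:`BiblioRecord` is one publication as exported from a bibliographic
database (Scopus-style): text fields, entity lists (authors, institutions,
countries, keywords) and a citation count.  A :class:`Corpus` is an ordered
collection of records plus a provenance report accumulated by the cleaning
steps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Iterator

DOC_TYPES = ("article", "review", "other")

#: entity levels understood by counting and network construction
ENTITY_LEVELS = ("author", "institution", "country", "keyword")


@dataclass
class BiblioRecord:
    """One publication."""

    record_id: str
    title: str
    abstract: str
    year: int
    doc_type: str = "other"
    language: str = "English"
    doi: str | None = None
    authors: list[str] = field(default_factory=list)
    institutions: list[str] = field(default_factory=list)
    countries: list[str] = field(default_factory=list)
    author_keywords: list[str] = field(default_factory=list)
    index_keywords: list[str] = field(default_factory=list)
    citation_count: int = 0

    def __post_init__(self) -> None:
        if self.citation_count < 0:
            raise ValueError(
                f"record {self.record_id}: citation_count must be >= 0"
            )
        if self.doc_type not in DOC_TYPES:
            self.doc_type = "other"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiblioRecord":
        return cls(**d)


def record_entities(record: BiblioRecord, level: str) -> list[str]:
    """Entities listed by *record* at *level*.

    ``keyword`` merges author and index keywords (the "total keywords" of a
    co-occurrence analysis); ``keyword_author`` / ``keyword_index`` select one
    list.  ``doc_type`` and ``language`` yield the single categorical value.
    """
    if level == "author":
        return list(record.authors)
    if level == "institution":
        return list(record.institutions)
    if level == "country":
        return list(record.countries)
    if level == "keyword" or level == "keyword_both":
        return list(record.author_keywords) + list(record.index_keywords)
    if level == "keyword_author":
        return list(record.author_keywords)
    if level == "keyword_index":
        return list(record.index_keywords)
    if level == "doc_type":
        return [record.doc_type]
    if level == "language":
        return [record.language]
    raise ValueError(f"unknown entity level: {level!r}")


@dataclass
class Corpus:
    """An ordered list of records plus a cleaning/provenance report."""

    records: list[BiblioRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BiblioRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def year_range(self) -> tuple[int, int]:
        if not self.records:
            raise ValueError("empty corpus has no year range")
        years = [r.year for r in self.records]
        return min(years), max(years)

    def validate(self) -> None:
        """Check corpus-level invariants (unique ids, unique DOIs)."""
        seen_ids: set[str] = set()
        seen_dois: set[str] = set()
        for r in self.records:
            if r.record_id in seen_ids:
                raise ValueError(f"duplicate record_id {r.record_id!r}")
            seen_ids.add(r.record_id)
            if r.doi:
                key = r.doi.strip().lower()
                if key in seen_dois:
                    raise ValueError(f"duplicate DOI {r.doi!r}")
                seen_dois.add(key)


class AliasMapError(ValueError):
    """Raised for an invalid (non-idempotent) alias map."""


@dataclass
class AliasMap:
    """Variant -> canonical name mapping for one entity level.

    The mapping must be idempotent: every canonical value maps to itself
    (explicitly or by absence).
    """

    entity_level: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity_level not in ENTITY_LEVELS:
            raise AliasMapError(
                f"entity_level must be one of {ENTITY_LEVELS}, "
                f"got {self.entity_level!r}"
            )
        for variant, canonical in self.mapping.items():
            target = self.mapping.get(canonical, canonical)
            if target != canonical:
                raise AliasMapError(
                    f"alias map not idempotent: {variant!r} -> {canonical!r} "
                    f"-> {target!r}"
                )

    def resolve(self, name: str) -> str:
        return self.mapping.get(name, name)


_TITLE_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_title(title: str) -> str:
    """Lowercase, strip punctuation and collapse whitespace (dedup key)."""
    t = _TITLE_PUNCT.sub(" ", title.lower())
    return _WS.sub(" ", t).strip()
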