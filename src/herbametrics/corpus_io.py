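"""Reading, validating, deduplicating and normalizing bibliographic exports.

Input is a Scopus-style CSV export (one row per publication, quoted fields,
``"; "``-delimited multi-value cells).  The canonical on-disk form of a
cleaned corpus is JSON-lines, one record per line.

Cleaning mirrors the usual bibliometric workflow: parse and validate rows
(rejecting, not dropping, rows with an unparseable year), remove duplicate
records (DOI key first, then a normalized title + year key), and map entity
name variants onto canonical forms through an explicit alias map.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .records import AliasMap, BiblioRecord, Corpus, normalize_title, record_entities

__all__ = [
    "read_bibliographic_csv",
    "write_corpus_csv",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "deduplicate",
    "normalize_entities",
    "filter_by_period",
    "DEFAULT_COLUMN_MAP",
    "load_country_gazetteer",
]


class CorpusFormatError(ValueError):
    """Raised for malformed or empty bibliographic input."""


#: canonical field -> Scopus export column header
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "record_id": "Record ID",          # optional; synthesized when absent
    "doi": "DOI",
    "title": "Title",
    "abstract": "Abstract",
    "year": "Year",
    "doc_type": "Document Type",
    "language": "Language of Original Document",
    "authors": "Authors",
    "affiliations": "Affiliations",
    "institutions": "Institutions",    # optional; parsed from affiliations when absent
    "countries": "Countries",          # optional; parsed from affiliations when absent
    "author_keywords": "Author Keywords",
    "index_keywords": "Index Keywords",
    "citation_count": "Cited by",
}

#: columns that must be resolvable in every export
_REQUIRED = ("title", "abstract", "year", "authors")

_DOC_TYPE_ALIASES = {
    "article": "article",
    "review": "review",
}


def load_country_gazetteer() -> set[str]:
    """Country names used to recognize the country token of an affiliation."""
    text = resources.files("herbametrics.data").joinpath("countries.txt").read_text(
        encoding="utf-8"
    )
    return {line.strip() for line in text.splitlines() if line.strip()}


def _split_multi(cell: str | float | None, delimiter: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    parts = [p.strip() for p in str(cell).split(delimiter)]
    return [p for p in parts if p]


def _parse_affiliations(
    cell: str | None, delimiter: str, gazetteer: set[str]
) -> tuple[list[str], list[str]]:
    """Institution and country lists from an affiliation cell.

    Scopus convention: affiliations are ``"; "``-separated, each a
    comma-separated chain ending in the country.  The institution is taken as
    the first comma token, the country as the last comma token when it matches
    the gazetteer.
    """
    institutions: list[str] = []
    countries: list[str] = []
    for aff in _split_multi(cell, delimiter):
        tokens = [t.strip() for t in aff.split(",") if t.strip()]
        if not tokens:
            continue
        institutions.append(tokens[0])
        if tokens[-1] in gazetteer:
            countries.append(tokens[-1])
    return institutions, countries


def _dedup_preserve(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def read_bibliographic_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str = "; ",
) -> Corpus:
    """Parse a Scopus-style CSV export into a :class:`Corpus`.

    Rows whose year cannot be parsed as an integer are routed to the
    ``rejects`` list of the provenance report rather than silently dropped.

    Raises
    ------
    CorpusFormatError
        If the file is empty or a required column is missing (the error names
        the column).
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8",
                         encoding_errors="replace")
    except pd.errors.EmptyDataError:
        raise CorpusFormatError(f"empty corpus file: {path}") from None
    if df.empty:
        raise CorpusFormatError(f"empty corpus file: {path}")

    for field in _REQUIRED:
        if colmap[field] not in df.columns:
            raise CorpusFormatError(
                f"required column {colmap[field]!r} (field {field!r}) "
                f"missing from {path}"
            )

    gazetteer = load_country_gazetteer()
    have = {f: colmap[f] in df.columns for f in colmap}

    def cell(row, field):
        return row[colmap[field]] if have[field] else ""

    records: list[BiblioRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        raw_year = str(cell(row, "year")).strip()
        try:
            year = int(float(raw_year))
        except ValueError:
            rejects.append({"row": i, "year": raw_year,
                            "title": str(cell(row, "title"))})
            continue

        if have["institutions"] and have["countries"]:
            institutions = _split_multi(cell(row, "institutions"), delimiter)
            countries = _split_multi(cell(row, "countries"), delimiter)
        else:
            institutions, countries = _parse_affiliations(
                cell(row, "affiliations"), delimiter, gazetteer
            )

        raw_cites = str(cell(row, "citation_count")).strip()
        citations = int(float(raw_cites)) if raw_cites else 0

        doc_type = _DOC_TYPE_ALIASES.get(
            str(cell(row, "doc_type")).strip().lower(), "other"
        )
        rid = str(cell(row, "record_id")).strip() or f"r{i:06d}"
        doi = str(cell(row, "doi")).strip() or None

        records.append(
            BiblioRecord(
                record_id=rid,
                doi=doi,
                title=str(cell(row, "title")),
                abstract=str(cell(row, "abstract")),
                year=year,
                doc_type=doc_type,
                language=str(cell(row, "language")).strip() or "English",
                authors=_dedup_preserve(_split_multi(cell(row, "authors"), delimiter)),
                institutions=_dedup_preserve(institutions),
                countries=_dedup_preserve(countries),
                author_keywords=_dedup_preserve(
                    _split_multi(cell(row, "author_keywords"), delimiter)
                ),
                index_keywords=_dedup_preserve(
                    _split_multi(cell(row, "index_keywords"), delimiter)
                ),
                citation_count=max(citations, 0),
            )
        )

    corpus = Corpus(records=records)
    corpus.provenance = {
        "source": str(path),
        "rows_read": int(len(df)),
        "rows_kept": len(records),
        "rejects": rejects,
    }
    return corpus


def write_corpus_csv(corpus: Corpus, path: str | Path, delimiter: str = "; ") -> None:
    """Write a corpus in the same CSV dialect :func:`read_bibliographic_csv` reads.

    Institutions and countries are written as explicit columns so the
    write -> read round trip is lossless.
    """
    path = Path(path)
    cols = DEFAULT_COLUMN_MAP
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = [cols[f] for f in (
            "record_id", "doi", "title", "abstract", "year", "doc_type",
            "language", "authors", "institutions", "countries",
            "author_keywords", "index_keywords", "citation_count",
        )]
        writer.writerow(header)
        for r in corpus:
            writer.writerow([
                r.record_id,
                r.doi or "",
                r.title,
                r.abstract,
                r.year,
                {"article": "Article", "review": "Review"}.get(r.doc_type, "Other"),
                r.language,
                delimiter.join(r.authors),
                delimiter.join(r.institutions),
                delimiter.join(r.countries),
                delimiter.join(r.author_keywords),
                delimiter.join(r.index_keywords),
                r.citation_count,
            ])


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Canonical corpus serialization: one JSON record per line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for r in corpus:
            fh.write(json.dumps(r.to_dict(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_corpus_jsonl(path: str | Path) -> Corpus:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(BiblioRecord.from_dict(json.loads(line)))
    return Corpus(records=records, provenance={"source": str(path)})


def _dedup_key(record: BiblioRecord) -> tuple:
    if record.doi:
        return ("doi", record.doi.strip().lower())
    return ("title", normalize_title(record.title), record.year)


def deduplicate(corpus: Corpus) -> Corpus:
    """Remove duplicate records.

    Key: DOI when present, else (normalized title, year).  Among duplicates
    the record with the largest citation count is kept; ties keep the first
    occurrence.  Output order follows the kept records' original order.
    """
    best: dict[tuple, int] = {}          # key -> index of kept record
    for i, r in enumerate(corpus.records):
        k = _dedup_key(r)
        if k not in best:
            best[k] = i
        elif r.citation_count > corpus.records[best[k]].citation_count:
            best[k] = i
    keep = sorted(best.values())
    removed = len(corpus.records) - len(keep)
    out = Corpus(records=[corpus.records[i] for i in keep])
    out.provenance = dict(corpus.provenance)
    out.provenance["duplicates_removed"] = removed
    out.provenance["rows_kept_after_dedup"] = len(keep)
    return out


def normalize_entities(corpus: Corpus, aliases: AliasMap) -> Corpus:
    """Replace entity name variants with canonical forms at one level.

    Within-record duplicates introduced by the mapping are collapsed
    (order-preserving).  Strings absent from the map pass through unchanged
    and are listed in the provenance report.  The ``keyword`` level applies to
    both author and index keywords.
    """
    level = aliases.entity_level
    unmapped: set[str] = set()

    def apply(names: list[str]) -> list[str]:
        out = []
        for n in names:
            c = aliases.resolve(n)
            if c == n and n not in aliases.mapping:
                unmapped.add(n)
            out.append(c)
        return _dedup_preserve(out)

    new_records = []
    for r in corpus:
        d = r.to_dict()
        if level == "author":
            d["authors"] = apply(r.authors)
        elif level == "institution":
            d["institutions"] = apply(r.institutions)
        elif level == "country":
            d["countries"] = apply(r.countries)
        elif level == "keyword":
            d["author_keywords"] = apply(r.author_keywords)
            d["index_keywords"] = apply(r.index_keywords)
        new_records.append(BiblioRecord.from_dict(d))

    out = Corpus(records=new_records, provenance=dict(corpus.provenance))
    report = out.provenance.setdefault("normalization", {})
    report[level] = {
        "aliases_defined": len(aliases.mapping),
        "unmapped_strings": sorted(unmapped),
    }
    return out


def filter_by_period(corpus: Corpus, start: int, end: int) -> Corpus:
    """Keep records with ``start <= year <= end`` (boundaries inclusive)."""
    if start > end:
        raise ValueError(f"invalid period: start {start} > end {end}")
    kept = [r for r in corpus if start <= r.year <= end]
    out = Corpus(records=kept, provenance=dict(corpus.provenance))
    out.provenance["period"] = [start, end]
    return out
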