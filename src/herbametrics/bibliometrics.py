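"""Descriptive bibliometric indicators.

Counting is *whole counting*: a record credits every distinct entity it
lists (country, institution, author) with one full publication, so shares
across co-listed entities may sum above 100%.  Ratios and shares are
rounded half-up to the number of decimals printed in bibliometric reports.
"""

from __future__ import annotations

from collections import Counter
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .records import Corpus, record_entities

__all__ = [
    "round_half_up",
    "citation_ratio",
    "share",
    "annual_counts",
    "entity_counts",
]

RANKABLE_LEVELS = ("country", "institution", "author", "doc_type", "language")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Python's builtin ``round`` is banker's rounding; printed bibliometric
    shares such as 88.5% round 0.5 up.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def citation_ratio(
    citation_total: float, publication_count: int, decimals: int | None = 1
) -> float:
    """Average citations per published record.

    Raises for a zero publication count rather than silently returning 0.
    ``decimals=None`` skips the reporting rounding.
    """
    if publication_count <= 0:
        raise ZeroDivisionError(
            "citation_ratio undefined for publication_count <= 0"
        )
    if citation_total < 0:
        raise ValueError("citation_total must be >= 0")
    ratio = citation_total / publication_count
    return ratio if decimals is None else round_half_up(ratio, decimals)


def share(count: int, total: int, decimals: int = 1) -> float:
    """Percentage ``100 * count / total``, rounded half-up to *decimals*."""
    if total <= 0:
        raise ValueError("share undefined for total <= 0")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, total={total}]")
    return round_half_up(100.0 * count / total, decimals)


def annual_counts(
    corpus: Corpus, level: str | None = None, top_k: int = 5
) -> pd.DataFrame:
    """Publications per year, zero-filled over the corpus year span.

    Always includes an ``"all"`` column; with *level* given, adds one column
    per top-*k* entity (whole counting: a record with two countries counts
    once for each).  The ``"all"`` column sums to the corpus size.
    """
    if len(corpus) == 0:
        raise ValueError("annual_counts undefined for an empty corpus")
    y0, y1 = corpus.year_range()
    years = list(range(y0, y1 + 1))
    table: dict[str, Counter] = {"all": Counter(r.year for r in corpus)}
    if level is not None:
        totals: Counter = Counter()
        per_entity: dict[str, Counter] = {}
        for r in corpus:
            for e in set(record_entities(r, level)):
                totals[e] += 1
                per_entity.setdefault(e, Counter())[r.year] += 1
        top = [e for e, _ in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))]
        for e in top[:top_k]:
            table[e] = per_entity[e]
    df = pd.DataFrame(
        {name: [cnt.get(y, 0) for y in years] for name, cnt in table.items()},
        index=pd.Index(years, name="year"),
    )
    return df


def entity_counts(corpus: Corpus, level: str, min_docs: int = 1) -> pd.DataFrame:
    """Ranked table of entities at *level* with at least *min_docs* records.

    Columns: ``entity, publication_count, citation_total, citation_ratio``
    (ratio rounded to 1 decimal), sorted by count descending with
    alphabetical tie order.
    """
    if level not in RANKABLE_LEVELS:
        raise ValueError(f"level must be one of {RANKABLE_LEVELS}, got {level!r}")
    pubs: Counter = Counter()
    cites: Counter = Counter()
    for r in corpus:
        for e in set(record_entities(r, level)):
            pubs[e] += 1
            cites[e] += r.citation_count
    rows = [
        (e, n, cites[e], citation_ratio(cites[e], n))
        for e, n in pubs.items()
        if n >= min_docs
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(
        rows, columns=["entity", "publication_count", "citation_total",
                       "citation_ratio"]
    )
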