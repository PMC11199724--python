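#!/usr/bin/env python
"""Descriptive bibliometrics: annual series, rankings, shares, ratios.

Reproduces the indicator set of a corpus-level bibliometric study on the
cleaned synthetic corpus: the annual publication series (checking where the
volume peaks), ranked country/institution/author tables with citation
ratios, and document-type shares.

Outputs: results/annual_counts.csv, results/ranking_<level>.csv
"""

from pathlib import Path

from herbametrics import annual_counts, entity_counts, read_corpus_jsonl, share

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corpus = read_corpus_jsonl(OUT / "corpus_clean.jsonl")
    n = len(corpus)

    annual = annual_counts(corpus, level="country", top_k=5)
    annual.to_csv(OUT / "annual_counts.csv")
    peak = int(annual["all"].idxmax())
    print(f"{n} records, {annual.index.min()}-{annual.index.max()}; "
          f"peak year {peak} (post-2010 surge: {peak > 2010})")

    for level in ("country", "institution", "author", "doc_type", "language"):
        table = entity_counts(corpus, level)
        table.to_csv(OUT / f"ranking_{level}.csv", index=False)

    countries = entity_counts(corpus, "country")
    print("\ntop countries (whole counting):")
    for row in countries.head(5).itertuples():
        print(f"  {row.entity:15s} {row.publication_count:4d} records "
              f"({share(row.publication_count, n):5.1f}%), "
              f"citation ratio {row.citation_ratio}")

    doc_types = entity_counts(corpus, "doc_type")
    print("\ndocument types:")
    for row in doc_types.itertuples():
        print(f"  {row.entity:8s} {row.publication_count:4d} "
              f"({share(row.publication_count, n):5.1f}%)")


if __name__ == "__main__":
    main()
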