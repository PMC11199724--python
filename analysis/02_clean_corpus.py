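#!/usr/bin/env python
"""Clean the raw corpus: deduplicate and normalize author names.

Reads results/corpus.csv, removes duplicate records (DOI key, then
normalized title + year), applies the ground-truth author alias map, and
reports how the counts reconcile.

Outputs: results/corpus_clean.jsonl, results/cleaning_report.json
"""

import json
from pathlib import Path

from herbametrics import (
    AliasMap,
    GroundTruth,
    deduplicate,
    normalize_entities,
    read_bibliographic_csv,
    write_corpus_jsonl,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corpus = read_bibliographic_csv(OUT / "corpus.csv")
    truth = GroundTruth.from_json(OUT / "ground_truth.json")
    n_raw = len(corpus)
    corpus = deduplicate(corpus)
    corpus = normalize_entities(
        corpus, AliasMap("author", dict(truth.name_variants)))
    write_corpus_jsonl(corpus, OUT / "corpus_clean.jsonl")
    (OUT / "cleaning_report.json").write_text(
        json.dumps(corpus.provenance, indent=2, sort_keys=True), encoding="utf-8")
    removed = corpus.provenance["duplicates_removed"]
    print(f"{n_raw} rows in; {removed} duplicates removed; {len(corpus)} kept "
          f"(input = kept + removed: {n_raw == len(corpus) + removed})")
    print(f"author aliases applied: {len(truth.name_variants)}")


if __name__ == "__main__":
    main()
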