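"""Synthetic bibliographic corpora with known ground truth.

The generator emulates the statistical shape of a 2002-2022 bibliographic
corpus on medicinal-plant research: a post-2010 surge in annual volume, a
skewed country mixture dominated by one country (~66% of records),
author-collaboration structure planted as blocks, per-record TRL labels
drawn from a target five-category distribution, and abstracts whose tokens
mix a per-category vocabulary (built around the shipped TRL anchor terms)
with a shared background vocabulary under a controllable overlap ``eps``.
Injected duplicates and author-name variants exercise the cleaning steps.

Every quantity a pipeline stage is supposed to recover is recorded in
:class:`GroundTruth`.  Abstracts are token soups, not natural language.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .networks import EntityGraph
from .records import BiblioRecord, Corpus
from .trl import Benchmark, TRLCategory, TRLKeywordSet, load_default_keywords

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_corpus",
    "make_benchmark",
    "planted_partition_graph",
    "DEFAULT_TRL_DISTRIBUTION",
]

#: five-category TRL mixture matching an observed corpus-level distribution
#: (shares ~1 / 45 / 4.5 / 25 / 24 %)
DEFAULT_TRL_DISTRIBUTION: dict[TRLCategory, float] = {
    TRLCategory.TRL1: 26 / 1849,
    TRLCategory.TRL2: 834 / 1849,
    TRLCategory.TRL3: 83 / 1849,
    TRLCategory.TRL4_5: 464 / 1849,
    TRLCategory.TRL6_9: 442 / 1849,
}

#: one dominant country at ~66%, mirroring the skew of the real literature
DEFAULT_COUNTRY_MIXTURE: dict[str, float] = {
    "Brazil": 0.659,
    "United States": 0.129,
    "Peru": 0.069,
    "Spain": 0.055,
    "France": 0.050,
    "Germany": 0.038,
}

_GLOBAL_KEYWORDS = (
    "medicinal plants", "amazon", "natural products", "essential oils",
    "leishmaniasis", "malaria", "antioxidant activity", "phytochemistry",
    "traditional medicine", "biodiversity", "plant extract", "chagas disease",
)


@dataclass
class SynthParams:
    """Generator settings; defaults are the study conditions being emulated."""

    n_records: int = 500
    year_range: tuple[int, int] = (2002, 2022)
    #: slope of the linear post-2010 volume ramp (weight 1 before 2011)
    surge_slope: float = 0.25
    country_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_MIXTURE)
    )
    p_second_country: float = 0.25
    n_authors: int = 60
    n_blocks: int = 6
    p_in: float = 0.9
    p_out: float = 0.05
    authors_per_record_mean: float = 3.0
    trl_distribution: dict[TRLCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_TRL_DISTRIBUTION)
    )
    #: filler terms per category vocabulary, on top of the anchor tokens
    category_vocab_size: int = 40
    background_vocab_size: int = 120
    #: fraction of abstract tokens drawn from the shared background vocabulary
    eps: float = 0.3
    #: guaranteed own-category anchor tokens per abstract (the label signal)
    n_anchor_tokens: int = 3
    abstract_length_mean: float = 60.0
    abstract_length_min: int = 30
    citation_mean: float = 15.0
    citation_dispersion: float = 1.0
    n_duplicates: int = 10
    n_name_variants: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks > self.n_authors:
            raise ValueError("infeasible params: n_blocks > n_authors")
        if self.p_in < self.p_out:
            raise ValueError("planted recovery requires p_in >= p_out")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("eps must lie in [0, 1]")
        for name, mix in (("country_mixture", self.country_mixture),
                          ("trl_distribution", self.trl_distribution)):
            total = sum(mix.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} must sum to 1, sums to {total}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has negative mass")
        if self.n_duplicates > self.n_records:
            raise ValueError("n_duplicates cannot exceed n_records")


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way pipeline stages report it."""

    trl_labels: dict[str, TRLCategory] = field(default_factory=dict)
    author_blocks: dict[str, int] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    name_variants: dict[str, str] = field(default_factory=dict)
    #: canonical author -> number of (non-duplicate) records listing them
    author_doc_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "trl_labels": {k: v.value for k, v in self.trl_labels.items()},
            "author_blocks": self.author_blocks,
            "duplicate_pairs": self.duplicate_pairs,
            "name_variants": self.name_variants,
            "author_doc_counts": self.author_doc_counts,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            trl_labels={k: TRLCategory.from_label(v)
                        for k, v in raw["trl_labels"].items()},
            author_blocks=raw["author_blocks"],
            duplicate_pairs=[tuple(p) for p in raw["duplicate_pairs"]],
            name_variants=raw["name_variants"],
            author_doc_counts=raw["author_doc_counts"],
        )


def _category_vocabularies(
    params: SynthParams, keywords: TRLKeywordSet
) -> tuple[dict[TRLCategory, list[str]], dict[TRLCategory, list[str]], list[str]]:
    """Anchor token lists, full per-category vocabularies, and background."""
    anchors = {c: sorted(keywords.token_set(c)) for c in TRLCategory}
    vocab = {
        c: anchors[c]
        + [f"{c.name.lower()}term{i:02d}" for i in range(params.category_vocab_size)]
        for c in TRLCategory
    }
    background = [f"bgterm{i:03d}" for i in range(params.background_vocab_size)]
    return anchors, vocab, background


def generate_corpus(
    params: SynthParams | None = None,
    keywords: TRLKeywordSet | None = None,
) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus of ``n_records + n_duplicates`` rows plus its truth.

    Deterministic for a fixed seed.  Abstracts consist of
    ``n_anchor_tokens`` guaranteed anchor tokens of the record's true TRL
    category followed by tokens drawn from the background vocabulary with
    probability ``eps`` and from the category vocabulary otherwise.
    Duplicates are appended after the originals: half exact-DOI copies, half
    DOI-less title-case variants (their originals are made DOI-less too), so
    both deduplication keys are exercised.
    """
    params = params or SynthParams()
    params.validate()
    keywords = keywords or load_default_keywords()
    rng = np.random.default_rng(params.seed)

    y0, y1 = params.year_range
    years = np.arange(y0, y1 + 1)
    weights = np.array(
        [1.0 if y <= 2010 else 1.0 + params.surge_slope * (y - 2010) for y in years]
    )
    weights = weights / weights.sum()

    countries = list(params.country_mixture)
    country_p = np.array([params.country_mixture[c] for c in countries])
    institutions = {c: [f"{c} Institute {k + 1}" for k in range(3)] for c in countries}

    author_names = [f"Author {i:03d}" for i in range(params.n_authors)]
    blocks = {a: i % params.n_blocks for i, a in enumerate(author_names)}
    by_block = [
        [a for a in author_names if blocks[a] == b] for b in range(params.n_blocks)
    ]

    cats = list(TRLCategory)
    cat_p = np.array([params.trl_distribution[c] for c in cats])
    anchors, vocab, background = _category_vocabularies(params, keywords)
    q_in = params.p_in / (params.p_in + params.p_out) if params.p_in > 0 else 0.0

    truth = GroundTruth(author_blocks=dict(blocks))
    records: list[BiblioRecord] = []
    for i in range(params.n_records):
        rid = f"syn{i:05d}"
        cat = cats[rng.choice(len(cats), p=cat_p)]
        truth.trl_labels[rid] = cat
        year = int(rng.choice(years, p=weights))

        rec_countries = [countries[rng.choice(len(countries), p=country_p)]]
        if rng.random() < params.p_second_country:
            other = countries[rng.choice(len(countries), p=country_p)]
            if other not in rec_countries:
                rec_countries.append(other)
        rec_insts = []
        for c in rec_countries:
            picks = rng.choice(3, size=int(rng.integers(1, 3)), replace=False)
            rec_insts.extend(institutions[c][k] for k in sorted(picks))

        home = int(rng.integers(params.n_blocks))
        n_auth = max(1, min(8, 1 + int(rng.poisson(params.authors_per_record_mean - 1))))
        rec_authors = [by_block[home][int(rng.integers(len(by_block[home])))]]
        while len(set(rec_authors)) < n_auth:
            if rng.random() < q_in:
                pool = by_block[home]
            else:
                b = int(rng.integers(params.n_blocks - 1))
                b = b if b < home else b + 1
                pool = by_block[b]
            rec_authors.append(pool[int(rng.integers(len(pool)))])
            if len(rec_authors) > 4 * n_auth:    # defensive: tiny blocks
                break
        rec_authors = list(dict.fromkeys(rec_authors))

        length = max(params.abstract_length_min,
                     int(rng.poisson(params.abstract_length_mean)))
        toks = [anchors[cat][int(rng.integers(len(anchors[cat])))]
                for _ in range(params.n_anchor_tokens)]
        for _ in range(length - len(toks)):
            if rng.random() < params.eps:
                toks.append(background[int(rng.integers(len(background)))])
            else:
                toks.append(vocab[cat][int(rng.integers(len(vocab[cat])))])

        kw_anchor = list(keywords.terms[cat])
        akw = [kw_anchor[k] for k in sorted(
            rng.choice(len(kw_anchor), size=min(2, len(kw_anchor)), replace=False))]
        akw += [_GLOBAL_KEYWORDS[k] for k in sorted(
            rng.choice(len(_GLOBAL_KEYWORDS), size=2, replace=False))]
        ikw = [_GLOBAL_KEYWORDS[k] for k in sorted(
            rng.choice(len(_GLOBAL_KEYWORDS), size=3, replace=False))]

        disp = params.citation_dispersion
        cites = int(rng.negative_binomial(
            disp, disp / (disp + params.citation_mean)))

        records.append(BiblioRecord(
            record_id=rid,
            doi=f"10.5555/synth.{i:05d}",
            title=f"Synthetic record {i:04d} on {vocab[cat][0]}",
            abstract=" ".join(toks),
            year=year,
            doc_type=str(rng.choice(["article", "review", "other"],
                                    p=[0.885, 0.072, 0.043])),
            language=str(rng.choice(["English", "Portuguese", "Spanish", "Other"],
                                    p=[0.895, 0.068, 0.029, 0.008])),
            authors=rec_authors,
            institutions=list(dict.fromkeys(rec_insts)),
            countries=rec_countries,
            author_keywords=list(dict.fromkeys(akw)),
            index_keywords=ikw,
            citation_count=cites,
        ))

    # author-name variants, injected before duplication so copies inherit them
    variant_authors = [author_names[k] for k in sorted(
        rng.choice(params.n_authors,
                   size=min(params.n_name_variants, params.n_authors),
                   replace=False))]
    for a in variant_authors:
        variant = a.replace("Author", "Auth.")
        truth.name_variants[variant] = a
        for r in records:
            if a in r.authors and rng.random() < 0.5:
                r.authors[r.authors.index(a)] = variant

    for r in records:
        for a in r.authors:
            canonical = truth.name_variants.get(a, a)
            truth.author_doc_counts[canonical] = (
                truth.author_doc_counts.get(canonical, 0) + 1
            )

    if params.n_duplicates:
        dup_idx = sorted(rng.choice(params.n_records, size=params.n_duplicates,
                                    replace=False))
        half = params.n_duplicates // 2
        for j, idx in enumerate(dup_idx):
            orig = records[idx]
            d = orig.to_dict()
            d["record_id"] = f"dup{j:04d}"
            if j >= half:                      # title-case variants, DOI-less
                orig.doi = None
                d["doi"] = None
                d["title"] = d["title"].upper()
            copy = BiblioRecord.from_dict(d)
            records.append(copy)
            truth.duplicate_pairs.append((orig.record_id, copy.record_id))

    corpus = Corpus(records=records, provenance={
        "source": "synthetic",
        "seed": params.seed,
        "n_records": params.n_records,
        "n_duplicates": params.n_duplicates,
    })
    return corpus, truth


def make_benchmark(truth: GroundTruth, n_labeled: int, seed: int = 0) -> Benchmark:
    """Uniform random sample (without replacement) of labeled records,
    emulating a manually classified benchmark subset."""
    ids = sorted(truth.trl_labels)
    if n_labeled > len(ids):
        raise ValueError(
            f"requested {n_labeled} labels but only {len(ids)} records exist"
        )
    rng = np.random.default_rng(seed)
    picked = [ids[k] for k in sorted(rng.choice(len(ids), size=n_labeled,
                                                replace=False))]
    return Benchmark(labels={rid: truth.trl_labels[rid] for rid in picked})


def planted_partition_graph(
    n_blocks: int, block_size: int, p_in: float, p_out: float, seed: int = 0
) -> tuple[EntityGraph, dict[int, int]]:
    """Planted-partition benchmark graph for community-recovery tests.

    Returns the graph (unit weights, publication_count 1) and the planted
    node -> block membership.
    """
    g = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out, seed=seed)
    membership = {n: n // block_size for n in g.nodes}
    h = nx.Graph()
    for n in g.nodes:
        h.add_node(n, publication_count=1)
    for a, b in g.edges:
        if a != b:
            h.add_edge(a, b, weight=1)
    return EntityGraph(graph=h, level="author"), membership
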