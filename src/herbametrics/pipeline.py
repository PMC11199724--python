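"""End-to-end pipeline: clean -> metrics -> networks -> TRL -> summary.

A :class:`RunConfig` captures every knob of a run (periods, node thresholds,
TRL settings, seeds).  :func:`run_pipeline` executes the stages, writes CSV
tables, GEXF graphs and classification results under an output directory,
and returns a machine-readable summary that is byte-identical across re-runs
with the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bibliometrics, corpus_io, networks, trl
from .records import Corpus

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

#: node-count thresholds used for the standard network analyses
DEFAULT_THRESHOLDS = {"country": 10, "institution": 10, "author": 5, "keyword": 10}
#: standard reporting periods: full span plus the two halves of the series
DEFAULT_PERIODS = [[2002, 2022], [2002, 2012], [2013, 2022]]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    corpus_path: str
    out_dir: str
    periods: list[list[int]] = field(default_factory=lambda: [list(p) for p in DEFAULT_PERIODS])
    thresholds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    network_levels: tuple[str, ...] = ("country", "institution", "author")
    top_k: int = 5
    trl_measure: str = "jaccard"            # a measure name, or "select"
    trl_keywords_path: str | None = None    # None -> shipped anchor sets
    benchmark_path: str | None = None       # needed when trl_measure == "select"
    lda_k: int = 20
    lda_iterations: int = 200
    top_m: int = 0
    theta_min: float = 0.25
    seed: int = 0
    fit_lda: bool | None = None             # None -> only when needed

    def validate(self) -> None:
        for start, end in self.periods:
            if start > end:
                raise ValueError(f"malformed period [{start}, {end}]")
        for level, t in self.thresholds.items():
            if t < 1:
                raise ValueError(f"threshold for {level} must be >= 1, got {t}")
        if self.trl_measure != "select" and self.trl_measure not in trl.DISTANCE_MEASURES:
            raise ValueError(f"unknown trl_measure {self.trl_measure!r}")
        if self.trl_measure == "select" and not self.benchmark_path:
            raise ValueError("trl_measure 'select' requires a benchmark_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("clean")
def _clean(config: RunConfig) -> Corpus:
    path = Path(config.corpus_path)
    if path.suffix == ".jsonl":
        corpus = corpus_io.read_corpus_jsonl(path)
    else:
        corpus = corpus_io.read_bibliographic_csv(path)
    corpus = corpus_io.deduplicate(corpus)
    logger.info("clean: %d records kept", len(corpus))
    return corpus


@_stage("metrics")
def _metrics(config: RunConfig, corpus: Corpus, out: Path) -> dict:
    summary = {}
    annual = bibliometrics.annual_counts(corpus, level="country",
                                         top_k=config.top_k)
    annual.to_csv(out / "annual_counts.csv")
    summary["peak_year"] = int(annual["all"].idxmax())
    tables = {}
    for level in ("country", "institution", "author", "doc_type", "language"):
        t = bibliometrics.entity_counts(corpus, level)
        t.to_csv(out / f"ranking_{level}.csv", index=False)
        tables[level] = [
            {"entity": str(r.entity),
             "publication_count": int(r.publication_count),
             "citation_total": int(r.citation_total),
             "citation_ratio": float(r.citation_ratio),
             "share": bibliometrics.share(int(r.publication_count), len(corpus))}
            for r in t.head(config.top_k).itertuples()
        ]
    summary["top_entities"] = tables
    return summary


@_stage("networks")
def _networks(config: RunConfig, corpus: Corpus, out: Path, tag: str) -> dict:
    summary = {}
    for level in config.network_levels:
        g = networks.build_coauthorship_graph(
            corpus, level, min_docs=config.thresholds.get(level, 1))
        entry = {"n_nodes": g.n_nodes, "n_edges": g.n_edges}
        if g.n_edges > 0:
            part = networks.detect_communities(g, seed=config.seed)
            entry["n_communities"] = part.n_communities
            entry["modularity"] = round(part.modularity_q, 6)
            networks.export_graph(g, out / f"net_{tag}_{level}.gexf",
                                  partition=part, fmt="gexf")
        summary[level] = entry
    kg = networks.build_keyword_cooccurrence(
        corpus, which="both", min_occurrence=config.thresholds.get("keyword", 1))
    entry = {"n_nodes": kg.n_nodes, "n_edges": kg.n_edges}
    if kg.n_edges > 0:
        part = networks.detect_communities(kg, seed=config.seed)
        entry["n_communities"] = part.n_communities
        entry["modularity"] = round(part.modularity_q, 6)
        networks.export_graph(kg, out / f"net_{tag}_keyword.gexf",
                              partition=part, fmt="gexf")
    summary["keyword"] = entry
    return summary


@_stage("trl")
def _trl(config: RunConfig, corpus: Corpus, out: Path) -> dict:
    keywords = (trl.TRLKeywordSet.from_yaml(config.trl_keywords_path)
                if config.trl_keywords_path else trl.load_default_keywords())
    needs_model = (config.trl_measure != "jaccard"
                   or config.trl_measure == "select"
                   or config.top_m > 0)
    if config.fit_lda is not None:
        needs_model = config.fit_lda
    model = None
    if needs_model:
        model = trl.fit_topic_model(corpus, k=config.lda_k, seed=config.seed,
                                    iterations=config.lda_iterations)
    summary: dict = {}
    measure = config.trl_measure
    if measure == "select":
        benchmark = trl.Benchmark.from_csv(config.benchmark_path)
        measure, errors = trl.select_measure(
            corpus, keywords, model, benchmark,
            top_m=config.top_m, theta_min=config.theta_min)
        summary["measure_errors"] = {m: round(e, 6) for m, e in errors.items()}
    result = trl.classify_corpus(corpus, keywords, model, measure=measure,
                                 top_m=config.top_m, theta_min=config.theta_min)
    result.to_csv(out / "trl_classification.csv")
    dist = trl.trl_distribution(result)
    dist.to_csv(out / "trl_distribution.csv", index=False)
    summary["measure"] = measure
    summary["n_classified"] = len(result)
    summary["n_unclassifiable"] = len(result.unclassifiable)
    summary["distribution"] = {
        row.category: {"count": int(row.count), "share": float(row.share)}
        for row in dist.itertuples()
    }
    if config.benchmark_path and config.trl_measure != "select":
        benchmark = trl.Benchmark.from_csv(config.benchmark_path)
        report = trl.evaluate(result, benchmark)
        summary["benchmark_error"] = round(report.error_rate, 6)
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the results bundle under ``config.out_dir``.

    Returns the summary dict; ``summary.json`` on disk is serialized with
    sorted keys so identical configs give byte-identical output.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    corpus = _clean(config)
    corpus_io.write_corpus_jsonl(corpus, out / "corpus.jsonl")

    summary: dict = {
        "config": {
            "corpus_path": str(config.corpus_path),
            "periods": config.periods,
            "thresholds": config.thresholds,
            "trl_measure": config.trl_measure,
            "lda_k": config.lda_k,
            "seed": config.seed,
        },
        "corpus_size": len(corpus),
        "provenance": {k: v for k, v in corpus.provenance.items()
                       if k != "rejects"},
        "periods": {},
    }
    summary["metrics"] = _metrics(config, corpus, out)

    for start, end in config.periods:
        sub = corpus_io.filter_by_period(corpus, start, end)
        tag = f"{start}_{end}"
        psum = {"n_records": len(sub)}
        if len(sub):
            psum["networks"] = _networks(config, sub, out, tag)
        summary["periods"][tag] = psum

    summary["trl"] = _trl(config, corpus, out)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
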