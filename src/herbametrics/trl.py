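"""Technology Readiness Level (TRL) classification of abstracts.

The TRL scale grades technological maturity from basic research (level 1)
to post-marketing surveillance (level 9).  For herbal-medicine R&D visible
in publications the nine levels collapse into five usable categories:

* ``TRL1``   - basic research identifying extracts
* ``TRL2``   - isolation, fractionation, chemical characterization
* ``TRL3``   - in vitro / in silico testing
* ``TRL4-5`` - in vivo animal testing, formulation, patenting readiness
* ``TRL6-9`` - clinical trials of any phase (incl. population-response
  studies of traditional use)

Classification is unsupervised: each category is anchored by a small set of
keyword terms, each abstract is represented either as its token set
(optionally expanded with the top words of its dominant LDA topics) or as
its LDA topic distribution, and the predicted category is the argmin of a
distance between the two representations.  Four distances are supported -
Jaccard on sets, and Hellinger / Kullback-Leibler / Jensen-Shannon on topic
distributions.  A small hand-labeled benchmark is used only to *select* the
distance measure, never to train.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.special import rel_entr
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer, ENGLISH_STOP_WORDS

from .records import BiblioRecord, Corpus

__all__ = [
    "TRLCategory",
    "TRLKeywordSet",
    "TopicModel",
    "Benchmark",
    "ClassificationResult",
    "EvaluationReport",
    "preprocess",
    "fit_topic_model",
    "document_representation",
    "category_representation",
    "distance",
    "classify_record",
    "classify_corpus",
    "evaluate",
    "select_measure",
    "trl_distribution",
    "load_default_keywords",
]

DISTANCE_MEASURES = ("hellinger", "kullback_leibler", "jensen_shannon", "jaccard")
#: tie order when two measures reach the same benchmark error
MEASURE_PREFERENCE = ("jaccard", "jensen_shannon", "hellinger", "kullback_leibler")
SET_MEASURES = ("jaccard",)
KL_EPS = 1e-10


class TRLCategory(enum.Enum):
    """Five grouped TRL categories, ordered from least to most mature."""

    TRL1 = "TRL1"
    TRL2 = "TRL2"
    TRL3 = "TRL3"
    TRL4_5 = "TRL4-5"
    TRL6_9 = "TRL6-9"

    @property
    def rank(self) -> int:
        return list(TRLCategory).index(self)

    @classmethod
    def from_label(cls, label: str) -> "TRLCategory":
        label = label.strip().upper().replace("_", "-")
        for c in cls:
            if c.value == label or c.name == label.replace("-", "_"):
                return c
        raise ValueError(f"unknown TRL category label {label!r}")


CATEGORY_DESCRIPTIONS = {
    TRLCategory.TRL1: "basic research; identification of extracts",
    TRLCategory.TRL2: "isolation of substances, fractionation, "
                      "chemical characterization",
    TRLCategory.TRL3: "in vitro and in silico testing",
    TRLCategory.TRL4_5: "in vivo animal testing; formulation research and "
                        "readiness to patent (grouped)",
    TRLCategory.TRL6_9: "clinical trials, phases I-IV, including "
                        "population-response studies (grouped)",
}


class RepresentationError(ValueError):
    """A record or category cannot be represented (empty tokens / OOV anchors)."""


_TOKEN_RE = re.compile(r"[a-z0-9]+")
_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)


def preprocess(text: str) -> list[str]:
    """Deterministic tokenization: lowercase, strip punctuation, drop
    English stopwords and tokens shorter than 2 characters."""
    if not text:
        return []
    return [
        tok
        for tok in _TOKEN_RE.findall(text.lower())
        if len(tok) >= 2 and tok not in _STOPWORDS
    ]


@dataclass
class TRLKeywordSet:
    """Anchor terms per TRL category.

    Terms are lowercase uni/bi-grams; matching happens on their content
    tokens, so "in vitro" anchors the token "vitro".  Two categories may
    share terms, but identical whole sets are rejected as a configuration
    error.
    """

    terms: dict[TRLCategory, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = [c for c in TRLCategory if not self.terms.get(c)]
        if missing:
            raise ValueError(f"empty anchor set for {[c.value for c in missing]}")
        sets = {c: frozenset(self.terms[c]) for c in TRLCategory}
        for a in TRLCategory:
            for b in TRLCategory:
                if a.rank < b.rank and sets[a] == sets[b]:
                    raise ValueError(
                        f"identical anchor sets for {a.value} and {b.value}"
                    )

    def token_set(self, category: TRLCategory) -> frozenset:
        toks: set[str] = set()
        for term in self.terms[category]:
            toks.update(preprocess(term))
        return frozenset(toks)

    def pseudo_document(self, category: TRLCategory) -> list[str]:
        toks: list[str] = []
        for term in self.terms[category]:
            toks.extend(preprocess(term))
        return toks

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TRLKeywordSet":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TRLKeywordSet":
        terms = {
            TRLCategory.from_label(k): tuple(str(t).lower() for t in v)
            for k, v in raw.items()
        }
        return cls(terms=terms)


def load_default_keywords() -> TRLKeywordSet:
    """The anchor sets shipped with the package."""
    text = resources.files("herbametrics.data").joinpath(
        "trl_keywords.yaml"
    ).read_text(encoding="utf-8")
    return TRLKeywordSet.from_dict(yaml.safe_load(text))


@dataclass
class TopicModel:
    """A fitted LDA model: per-document θ and per-topic word distribution φ."""

    k: int
    doc_topic: np.ndarray            # (n_docs, K), rows sum to 1
    topic_word: np.ndarray           # (K, V), rows sum to 1
    vocabulary: list[str]
    doc_index: dict[str, int]        # record_id -> θ row
    seed: int
    iterations: int
    alpha: float
    beta: float
    _vectorizer: CountVectorizer = field(repr=False, default=None)
    _lda: LatentDirichletAllocation = field(repr=False, default=None)

    def theta(self, record_id: str) -> np.ndarray:
        return self.doc_topic[self.doc_index[record_id]]

    def infer(self, tokens: list[str]) -> np.ndarray:
        """Posterior topic distribution for an unseen token list."""
        x = self._vectorizer.transform([tokens])
        if x.sum() == 0:
            raise RepresentationError("all tokens out of model vocabulary")
        return self._lda.transform(x)[0]

    def in_vocabulary(self, tokens: list[str]) -> bool:
        return bool(self._vectorizer.transform([tokens]).sum() > 0)

    def top_words(self, topic: int, m: int) -> list[str]:
        idx = np.argsort(-self.topic_word[topic])[:m]
        return [self.vocabulary[i] for i in idx]


def fit_topic_model(
    corpus: Corpus,
    k: int = 20,
    seed: int = 0,
    iterations: int = 200,
    alpha: float | None = None,
    beta: float = 0.01,
) -> TopicModel:
    """Fit LDA (batch variational EM) on the preprocessed abstracts.

    Records with empty token lists are skipped; at least *k* non-empty
    documents are required.  ``alpha`` defaults to ``1/k``.
    """
    docs, ids = [], []
    for r in corpus:
        toks = preprocess(r.abstract)
        if toks:
            docs.append(toks)
            ids.append(r.record_id)
    if len(docs) < k:
        raise ValueError(
            f"need at least k={k} non-empty documents, have {len(docs)}"
        )
    alpha = 1.0 / k if alpha is None else alpha
    vectorizer = CountVectorizer(analyzer=lambda d: d, lowercase=False)
    x = vectorizer.fit_transform(docs)
    if x.shape[1] == 0:
        raise ValueError("empty vocabulary after preprocessing")
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        max_iter=iterations,
        learning_method="batch",
        random_state=seed,
    )
    doc_topic = lda.fit_transform(x)          # rows normalized by sklearn
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(
        k=k,
        doc_topic=doc_topic,
        topic_word=topic_word,
        vocabulary=list(vectorizer.get_feature_names_out()),
        doc_index={rid: i for i, rid in enumerate(ids)},
        seed=seed,
        iterations=iterations,
        alpha=alpha,
        beta=beta,
        _vectorizer=vectorizer,
        _lda=lda,
    )


def _record_theta(record: BiblioRecord, model: TopicModel) -> np.ndarray:
    if record.record_id in model.doc_index:
        return model.theta(record.record_id)
    return model.infer(preprocess(record.abstract))


def document_representation(
    record: BiblioRecord,
    model: TopicModel | None,
    mode: str = "token_set",
    top_m: int = 0,
    theta_min: float = 0.25,
):
    """Represent a record for distance computation.

    ``token_set`` mode returns the preprocessed token set, unioned with the
    top-*top_m* words of every topic whose θ weight is at least *theta_min*
    (the LDA expansion; ``top_m=0`` disables it and needs no model).
    ``topic_distribution`` mode returns the record's θ.
    """
    tokens = preprocess(record.abstract)
    if not tokens:
        raise RepresentationError(
            f"record {record.record_id}: empty abstract after preprocessing"
        )
    if mode == "token_set":
        rep = set(tokens)
        if top_m > 0:
            if model is None:
                raise ValueError("top_m > 0 requires a fitted topic model")
            theta = _record_theta(record, model)
            for topic in np.nonzero(theta >= theta_min)[0]:
                rep.update(model.top_words(int(topic), top_m))
        return frozenset(rep)
    if mode == "topic_distribution":
        if model is None:
            raise ValueError("topic_distribution mode requires a fitted model")
        return _record_theta(record, model)
    raise ValueError(f"unknown representation mode {mode!r}")


def category_representation(
    keywords: TRLKeywordSet, model: TopicModel | None, mode: str = "token_set"
) -> dict:
    """Per-category representation matching :func:`document_representation`.

    Set mode returns the anchor token sets themselves; distribution mode
    infers θ for each category's anchors concatenated as a pseudo-document.
    """
    if mode == "token_set":
        return {c: keywords.token_set(c) for c in TRLCategory}
    if mode == "topic_distribution":
        if model is None:
            raise ValueError("topic_distribution mode requires a fitted model")
        reps = {}
        for c in TRLCategory:
            pseudo = keywords.pseudo_document(c)
            if not model.in_vocabulary(pseudo):
                raise RepresentationError(
                    f"category {c.value}: anchors entirely out of the model "
                    f"vocabulary"
                )
            reps[c] = model.infer(pseudo)
        return reps
    raise ValueError(f"unknown representation mode {mode!r}")


# --------------------------------------------------------------------------
# distance measures

def _check_distributions(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise TypeError("distributions must be equal-length 1-d vectors")
    if (p < 0).any() or (q < 0).any():
        raise TypeError("distributions must be non-negative")
    if not (np.isclose(p.sum(), 1.0, atol=1e-6) and np.isclose(q.sum(), 1.0, atol=1e-6)):
        raise TypeError("distributions must sum to 1")
    return p, q


def hellinger(p, q) -> float:
    """H(p, q) = (1/sqrt(2)) * sqrt(sum (sqrt(p_i) - sqrt(q_i))^2), in [0, 1]."""
    p, q = _check_distributions(p, q)
    return float(np.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)) / np.sqrt(2.0))


def kullback_leibler(p, q, eps: float = KL_EPS) -> float:
    """KL(p || q) = sum p_i ln(p_i / (q_i + eps)), in nats; asymmetric, >= 0
    up to the smoothing term."""
    p, q = _check_distributions(p, q)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (q[mask] + eps))))


def jensen_shannon(p, q) -> float:
    """JS(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2; symmetric,
    in [0, ln 2] nats."""
    p, q = _check_distributions(p, q)
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def jaccard(a, b) -> float:
    """1 - |A ∩ B| / |A ∪ B| on sets; two empty sets are at distance 0."""
    if not isinstance(a, (set, frozenset)) or not isinstance(b, (set, frozenset)):
        raise TypeError("jaccard distance requires sets")
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


def distance(a, b, measure: str) -> float:
    """Dispatch to one of the four supported distance measures.

    Set and distribution arguments are type-checked: ``jaccard`` on
    distributions (or a distribution measure on sets) raises ``TypeError``.
    """
    if measure == "jaccard":
        return jaccard(a, b)
    if isinstance(a, (set, frozenset)) or isinstance(b, (set, frozenset)):
        raise TypeError(f"measure {measure!r} requires distributions, got sets")
    if measure == "hellinger":
        return hellinger(a, b)
    if measure == "kullback_leibler":
        return kullback_leibler(a, b)
    if measure == "jensen_shannon":
        return jensen_shannon(a, b)
    raise ValueError(f"unknown measure {measure!r}; expected {DISTANCE_MEASURES}")


# --------------------------------------------------------------------------
# classification

@dataclass
class Benchmark:
    """Hand-assigned TRL labels for a subset of records (measure selection)."""

    labels: dict[str, TRLCategory]

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Benchmark":
        labels = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                labels[row["record_id"]] = TRLCategory.from_label(row["category"])
        return cls(labels=labels)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["record_id", "category"])
            for rid, cat in self.labels.items():
                writer.writerow([rid, cat.value])


@dataclass
class ClassificationResult:
    """Predicted category and per-category distances for each record."""

    measure: str
    predictions: dict[str, TRLCategory] = field(default_factory=dict)
    distances: dict[str, dict[TRLCategory, float]] = field(default_factory=dict)
    unclassifiable: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.predictions)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["record_id", "category"]
                            + [f"d_{c.name}" for c in TRLCategory])
            for rid, cat in self.predictions.items():
                writer.writerow([rid, cat.value]
                                + [f"{self.distances[rid][c]:.6f}"
                                   for c in TRLCategory])


def _rep_mode(measure: str) -> str:
    return "token_set" if measure in SET_MEASURES else "topic_distribution"


def classify_record(
    record: BiblioRecord,
    category_reps: dict,
    model: TopicModel | None,
    measure: str,
    top_m: int = 0,
    theta_min: float = 0.25,
) -> tuple[TRLCategory, dict[TRLCategory, float]]:
    """Argmin-distance category for one record.

    Ties break toward the lower (less mature) category - the conservative
    maturity claim.
    """
    mode = _rep_mode(measure)
    doc = document_representation(record, model, mode=mode,
                                  top_m=top_m, theta_min=theta_min)
    dists = {c: distance(doc, category_reps[c], measure) for c in TRLCategory}
    best = min(TRLCategory, key=lambda c: (dists[c], c.rank))
    return best, dists


def classify_corpus(
    corpus: Corpus,
    keywords: TRLKeywordSet,
    model: TopicModel | None = None,
    measure: str = "jaccard",
    top_m: int = 0,
    theta_min: float = 0.25,
) -> ClassificationResult:
    """Classify every representable record; unrepresentable ones (empty
    abstracts) are counted as unclassifiable, never guessed."""
    if measure not in DISTANCE_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    category_reps = category_representation(keywords, model, mode=_rep_mode(measure))
    result = ClassificationResult(measure=measure)
    for r in corpus:
        try:
            cat, dists = classify_record(r, category_reps, model, measure,
                                         top_m=top_m, theta_min=theta_min)
        except RepresentationError:
            result.unclassifiable.append(r.record_id)
            continue
        result.predictions[r.record_id] = cat
        result.distances[r.record_id] = dists
    return result


@dataclass
class EvaluationReport:
    """Benchmark error rate and 5x5 confusion matrix (rows = true labels)."""

    error_rate: float
    confusion: np.ndarray
    n: int


def evaluate(result: ClassificationResult, benchmark: Benchmark) -> EvaluationReport:
    """Misclassification rate of *result* against the labeled benchmark."""
    if len(benchmark) == 0:
        raise ValueError("empty benchmark")
    missing = set(benchmark.labels) - set(result.predictions)
    if missing:
        raise ValueError(
            f"benchmark ids not classified: {sorted(missing)[:5]}"
        )
    cats = list(TRLCategory)
    confusion = np.zeros((5, 5), dtype=int)
    wrong = 0
    for rid, true_cat in benchmark.labels.items():
        pred = result.predictions[rid]
        confusion[cats.index(true_cat), cats.index(pred)] += 1
        wrong += int(pred is not true_cat)
    return EvaluationReport(
        error_rate=wrong / len(benchmark), confusion=confusion, n=len(benchmark)
    )


def select_measure(
    corpus: Corpus,
    keywords: TRLKeywordSet,
    model: TopicModel | None,
    benchmark: Benchmark,
    measures: tuple[str, ...] = DISTANCE_MEASURES,
    top_m: int = 0,
    theta_min: float = 0.25,
) -> tuple[str, dict[str, float]]:
    """Benchmark each candidate measure and return the one with minimum
    error (ties broken by the fixed preference order jaccard > JS >
    Hellinger > KL)."""
    if not measures:
        raise ValueError("need at least one candidate measure")
    errors: dict[str, float] = {}
    for m in measures:
        result = classify_corpus(corpus, keywords, model, measure=m,
                                 top_m=top_m, theta_min=theta_min)
        errors[m] = evaluate(result, benchmark).error_rate
    chosen = min(errors, key=lambda m: (errors[m], MEASURE_PREFERENCE.index(m)))
    return chosen, errors


def trl_distribution(result: ClassificationResult, decimals: int = 1):
    """Per-category counts and percentage shares of the classified records."""
    from .bibliometrics import share

    if len(result) == 0:
        raise ValueError("no classified records")
    counts = {c: 0 for c in TRLCategory}
    for cat in result.predictions.values():
        counts[cat] += 1
    total = len(result)
    import pandas as pd

    return pd.DataFrame(
        {
            "category": [c.value for c in TRLCategory],
            "count": [counts[c] for c in TRLCategory],
            "share": [share(counts[c], total, decimals) for c in TRLCategory],
        }
    )
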