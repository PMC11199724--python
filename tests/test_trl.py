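"""TRL classifier: preprocessing, LDA, distances, argmin classification."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from herbametrics import (
    Benchmark,
    Corpus,
    SynthParams,
    TRLCategory,
    TRLKeywordSet,
    classify_corpus,
    distance,
    evaluate,
    fit_topic_model,
    generate_corpus,
    load_default_keywords,
    make_benchmark,
    preprocess,
    select_measure,
    trl_distribution,
)
from herbametrics.trl import (
    RepresentationError,
    category_representation,
    classify_record,
    document_representation,
    hellinger,
    jaccard,
    jensen_shannon,
    kullback_leibler,
)

from conftest import make_record


def small_params(**kw):
    kw.setdefault("n_records", 120)
    kw.setdefault("n_duplicates", 0)
    kw.setdefault("n_name_variants", 0)
    return SynthParams(**kw)


class TestPreprocess:
    def test_stopwords_punctuation_and_case(self):
        assert preprocess("In vitro tests of the extract.") == \
            ["vitro", "tests", "extract"]

    def test_empty_text_gives_empty_list(self):
        assert preprocess("") == []
        assert preprocess("   \n ") == []

    def test_idempotent_on_fixture_texts(self):
        texts = ["In vitro tests of the extract.",
                 "Phase II clinical trial: efficacy & safety (n=40).",
                 "Isolation and fractionation of alkaloids from leaves"]
        for t in texts:
            toks = preprocess(t)
            assert preprocess(" ".join(toks)) == toks


class TestKeywordSet:
    def test_shipped_sets_cover_all_categories(self):
        kw = load_default_keywords()
        for c in TRLCategory:
            assert kw.token_set(c)

    def test_shipped_anchor_token_sets_pairwise_disjoint(self):
        # disjointness gives each category an unambiguous token signature
        kw = load_default_keywords()
        cats = list(TRLCategory)
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                assert not (kw.token_set(a) & kw.token_set(b))

    def test_empty_category_rejected(self):
        terms = {c: ("x",) for c in TRLCategory}
        terms[TRLCategory.TRL3] = ()
        with pytest.raises(ValueError, match="empty"):
            TRLKeywordSet(terms=terms)

    def test_identical_sets_rejected(self):
        terms = {c: (f"t{c.rank}",) for c in TRLCategory}
        terms[TRLCategory.TRL2] = terms[TRLCategory.TRL1]
        with pytest.raises(ValueError, match="identical"):
            TRLKeywordSet(terms=terms)


@pytest.fixture(scope="module")
def fitted():
    """Small corpus with a fitted K=5 model (module-scoped: LDA is the
    expensive step)."""
    corpus, truth = generate_corpus(small_params(eps=0.0, seed=21))
    model = fit_topic_model(corpus, k=5, seed=21, iterations=60)
    return corpus, truth, model


class TestTopicModel:
    def test_theta_and_phi_rows_normalized(self, fitted):
        _, _, model = fitted
        assert np.allclose(model.doc_topic.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(model.topic_word.sum(axis=1), 1.0, atol=1e-8)
        assert (model.doc_topic >= 0).all() and (model.topic_word >= 0).all()

    def test_reproducible_given_seed(self):
        corpus, _ = generate_corpus(small_params(seed=5))
        m1 = fit_topic_model(corpus, k=4, seed=9, iterations=30)
        m2 = fit_topic_model(corpus, k=4, seed=9, iterations=30)
        assert np.array_equal(m1.doc_topic, m2.doc_topic)

    def test_identical_documents_get_identical_theta(self):
        recs = [make_record(f"r{i}", abstract="isolation fractionation "
                            "purification compound alkaloid") for i in range(12)]
        model = fit_topic_model(Corpus(records=recs), k=3, seed=0, iterations=30)
        assert np.allclose(model.doc_topic, model.doc_topic[0], atol=1e-6)

    def test_disjoint_vocabularies_map_to_distinct_topics(self, fitted):
        # eps=0: each category vocabulary should dominate its own topic
        corpus, truth, model = fitted
        kw = load_default_keywords()
        top_topic = {}
        for c in TRLCategory:
            vocab_tokens = kw.token_set(c)
            ids = [r.record_id for r in corpus if truth.trl_labels[r.record_id] is c]
            if len(ids) < 3:
                continue
            theta = np.mean([model.theta(i) for i in ids], axis=0)
            top_topic[c] = int(theta.argmax())
        assert len(set(top_topic.values())) == len(top_topic)

    def test_too_few_documents_rejected(self):
        recs = [make_record("r0")]
        with pytest.raises(ValueError, match="at least"):
            fit_topic_model(Corpus(records=recs), k=5)


class TestRepresentations:
    def test_top_m_zero_is_plain_token_set(self, fitted):
        corpus, _, model = fitted
        r = corpus[0]
        rep = document_representation(r, model, "token_set", top_m=0)
        assert rep == frozenset(preprocess(r.abstract))

    def test_token_set_grows_monotonically_with_top_m(self, fitted):
        corpus, _, model = fitted
        r = corpus[0]
        prev = frozenset()
        for m in (0, 3, 6, 10):
            rep = document_representation(r, model, "token_set", top_m=m,
                                          theta_min=0.1)
            assert prev <= rep
            prev = rep

    def test_topic_distribution_sums_to_one(self, fitted):
        corpus, _, model = fitted
        rep = document_representation(corpus[0], model, "topic_distribution")
        assert rep.sum() == pytest.approx(1.0, abs=1e-8)

    def test_empty_abstract_is_unrepresentable(self, fitted):
        _, _, model = fitted
        r = make_record("empty", abstract="of the and")
        with pytest.raises(RepresentationError):
            document_representation(r, model, "token_set")

    def test_category_set_mode_is_identity_on_anchor_tokens(self):
        kw = load_default_keywords()
        reps = category_representation(kw, None, "token_set")
        assert reps[TRLCategory.TRL3] == kw.token_set(TRLCategory.TRL3)

    def test_category_distributions_normalized_and_separated(self, fitted):
        corpus, _, model = fitted
        kw = load_default_keywords()
        reps = category_representation(kw, model, "topic_distribution")
        cats = list(TRLCategory)
        for c in cats:
            assert reps[c].sum() == pytest.approx(1.0, abs=1e-8)
        # each category is closer (JS) to itself than to any other category
        for a in cats:
            for b in cats:
                if a is not b:
                    assert jensen_shannon(reps[a], reps[b]) > 0

    def test_oov_anchors_error_names_category(self, fitted):
        _, _, model = fitted
        terms = {c: tuple(f"neverseen{c.rank}{i}" for i in range(3))
                 for c in TRLCategory}
        kw = TRLKeywordSet(terms=terms)
        with pytest.raises(RepresentationError, match="TRL1"):
            category_representation(kw, model, "topic_distribution")


class TestDistances:
    def test_identity_of_indiscernibles(self):
        p = np.array([0.2, 0.3, 0.5])
        for measure in ("hellinger", "jensen_shannon", "kullback_leibler"):
            assert distance(p, p, measure) == pytest.approx(0.0, abs=1e-9)
        assert distance({"a", "b"}, {"a", "b"}, "jaccard") == 0.0

    def test_jaccard_arithmetic(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)
        assert jaccard({"a"}, {"b"}) == 1.0
        assert jaccard(set(), set()) == 0.0

    def test_js_disjoint_supports_equals_ln2(self):
        assert jensen_shannon([1.0, 0.0], [0.0, 1.0]) == pytest.approx(math.log(2))

    def test_hellinger_closed_form(self):
        assert hellinger([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.1846, abs=1e-4)
        assert hellinger([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_type_mismatch_rejected(self):
        with pytest.raises(TypeError):
            distance(np.array([0.5, 0.5]), np.array([0.5, 0.5]), "jaccard")
        with pytest.raises(TypeError):
            distance({"a"}, {"b"}, "hellinger")

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_symmetry_bounds_and_nonnegativity(self, xs, ys):
        n = min(len(xs), len(ys))
        p = np.array(xs[:n]) / sum(xs[:n])
        q = np.array(ys[:n]) / sum(ys[:n])
        h, js = hellinger(p, q), jensen_shannon(p, q)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert -1e-12 <= js <= math.log(2) + 1e-12
        assert h == pytest.approx(hellinger(q, p))
        assert js == pytest.approx(jensen_shannon(q, p))
        assert kullback_leibler(p, q) >= -1e-9


class TestClassify:
    def test_pure_anchor_abstract_classified_to_its_category(self):
        kw = load_default_keywords()
        r = make_record("r", abstract="isolation fractionation "
                        "chemical characterization")
        reps = category_representation(kw, None, "token_set")
        cat, dists = classify_record(r, reps, None, "jaccard")
        assert cat is TRLCategory.TRL2
        assert dists[TRLCategory.TRL2] == min(dists.values())

    def test_equidistant_record_ties_to_lowest_category(self):
        kw = load_default_keywords()
        r = make_record("r", abstract="unrelated words entirely elsewhere")
        reps = category_representation(kw, None, "token_set")
        cat, dists = classify_record(r, reps, None, "jaccard")
        assert len(set(dists.values())) == 1
        assert cat is TRLCategory.TRL1

    def test_duplicate_tokens_do_not_change_set_classification(self):
        kw = load_default_keywords()
        reps = category_representation(kw, None, "token_set")
        a = make_record("a", abstract="in vivo rats formulation")
        b = make_record("b", abstract="in vivo vivo rats rats rats formulation")
        assert classify_record(a, reps, None, "jaccard")[0] is \
            classify_record(b, reps, None, "jaccard")[0]

    def test_disjoint_vocabulary_corpus_recovered_exactly(self):
        corpus, truth = generate_corpus(small_params(eps=0.0, seed=31))
        result = classify_corpus(corpus, load_default_keywords(), None, "jaccard")
        assert all(result.predictions[rid] is truth.trl_labels[rid]
                   for rid in truth.trl_labels)

    def test_empty_abstracts_counted_not_guessed(self):
        recs = [make_record("good", abstract="in vitro assay"),
                make_record("bad", abstract="")]
        result = classify_corpus(Corpus(records=recs), load_default_keywords(),
                                 None, "jaccard")
        assert result.unclassifiable == ["bad"]
        assert set(result.predictions) == {"good"}


class TestEvaluate:
    def _result(self, preds):
        from herbametrics.trl import ClassificationResult
        r = ClassificationResult(measure="jaccard")
        r.predictions = preds
        return r

    def test_all_correct_is_zero(self):
        preds = {f"r{i}": TRLCategory.TRL2 for i in range(4)}
        bench = Benchmark(labels=dict(preds))
        assert evaluate(self._result(preds), bench).error_rate == 0.0

    def test_one_wrong_of_four(self):
        preds = {f"r{i}": TRLCategory.TRL2 for i in range(4)}
        bench = Benchmark(labels={**{f"r{i}": TRLCategory.TRL2 for i in range(3)},
                                  "r3": TRLCategory.TRL3})
        rep = evaluate(self._result(preds), bench)
        assert rep.error_rate == 0.25

    def test_confusion_matrix_bookkeeping(self):
        preds = {"a": TRLCategory.TRL1, "b": TRLCategory.TRL2,
                 "c": TRLCategory.TRL6_9}
        bench = Benchmark(labels={"a": TRLCategory.TRL1, "b": TRLCategory.TRL3,
                                  "c": TRLCategory.TRL6_9})
        rep = evaluate(self._result(preds), bench)
        # row sums = per-category true label counts
        assert rep.confusion.sum(axis=1).tolist() == [1, 0, 1, 0, 1]
        # trace identity: error = 1 - trace/n
        assert rep.error_rate == pytest.approx(
            1.0 - rep.confusion.trace() / rep.n)

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            evaluate(self._result({}), Benchmark(labels={}))


class TestSelectMeasure:
    def test_single_candidate_returned(self):
        corpus, truth = generate_corpus(small_params(eps=0.0, seed=41))
        bench = make_benchmark(truth, 30, seed=1)
        chosen, errors = select_measure(corpus, load_default_keywords(), None,
                                        bench, measures=("jaccard",))
        assert chosen == "jaccard" and set(errors) == {"jaccard"}

    def test_tie_broken_by_fixed_preference_order(self):
        corpus, truth = generate_corpus(small_params(eps=0.0, seed=43))
        model = fit_topic_model(corpus, k=5, seed=43, iterations=60)
        bench = make_benchmark(truth, 40, seed=2)
        chosen, errors = select_measure(corpus, load_default_keywords(), model,
                                        bench)
        best = min(errors.values())
        tied = [m for m, e in errors.items() if e == best]
        order = ("jaccard", "jensen_shannon", "hellinger", "kullback_leibler")
        assert chosen == min(tied, key=order.index)

    def test_jaccard_wins_when_signal_is_pure_set_overlap(self):
        # bodies drawn entirely from the shared background vocabulary; only
        # the injected anchor tokens carry the label
        uniform = {c: 0.2 for c in TRLCategory}
        wins = 0
        for seed in range(3):
            corpus, truth = generate_corpus(small_params(
                eps=1.0, n_anchor_tokens=3, trl_distribution=uniform,
                seed=100 + seed))
            model = fit_topic_model(corpus, k=5, seed=seed, iterations=40)
            bench = make_benchmark(truth, 50, seed=seed)
            chosen, errors = select_measure(corpus, load_default_keywords(),
                                            model, bench)
            if errors["jaccard"] == min(errors.values()):
                wins += 1
        assert wins == 3


class TestTrlDistribution:
    def test_degenerate_single_category(self):
        from herbametrics.trl import ClassificationResult
        r = ClassificationResult(measure="jaccard")
        r.predictions = {f"r{i}": TRLCategory.TRL2 for i in range(10)}
        dist = trl_distribution(r)
        row = dist[dist.category == "TRL2"].iloc[0]
        assert row["count"] == 10 and row["share"] == 100.0

    def test_observed_count_profile_rounds_to_reported_shares(self):
        from herbametrics.trl import ClassificationResult
        counts = {TRLCategory.TRL1: 26, TRLCategory.TRL2: 834,
                  TRLCategory.TRL3: 83, TRLCategory.TRL4_5: 464,
                  TRLCategory.TRL6_9: 442}
        preds = {}
        i = 0
        for cat, n in counts.items():
            for _ in range(n):
                preds[f"r{i}"] = cat
                i += 1
        r = ClassificationResult(measure="jaccard")
        r.predictions = preds
        dist = trl_distribution(r, decimals=0)
        assert dist["count"].sum() == len(preds)
        assert dist.share.tolist() == [1.0, 45.0, 4.0, 25.0, 24.0]

    def test_per_country_crosstab_row_sums(self):
        corpus, truth = generate_corpus(small_params(eps=0.0, seed=51))
        result = classify_corpus(corpus, load_default_keywords(), None, "jaccard")
        from collections import Counter
        by_country = Counter()
        crosstab = Counter()
        for r in corpus:
            for c in r.countries:
                by_country[c] += 1
                crosstab[c, result.predictions[r.record_id]] += 1
        for c in by_country:
            assert sum(crosstab[c, cat] for cat in TRLCategory) == by_country[c]


class TestRecoveryCurve:
    def test_error_non_decreasing_in_vocabulary_overlap(self):
        """Mean classification error over seeds must not decrease as the
        background-overlap fraction grows."""
        eps_grid = (0.0, 0.2, 0.4, 0.6)
        means = []
        for eps in eps_grid:
            errs = []
            for seed in range(5):
                corpus, truth = generate_corpus(small_params(
                    n_records=150, eps=eps, seed=1000 + seed))
                result = classify_corpus(corpus, load_default_keywords(),
                                         None, "jaccard")
                bench = Benchmark(labels=truth.trl_labels)
                errs.append(evaluate(result, bench).error_rate)
            means.append(sum(errs) / len(errs))
        assert means[0] == 0.0
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
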