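import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from herbametrics import BiblioRecord, Corpus, SynthParams, generate_corpus


def make_record(rid, **kwargs):
    defaults = dict(
        record_id=rid,
        title=f"Title {rid}",
        abstract="in vitro assay of the plant extract",
        year=2015,
        doc_type="article",
        authors=["A"],
        countries=["Brazil"],
        institutions=["Inst"],
        author_keywords=["k1"],
        index_keywords=["k2"],
        citation_count=0,
    )
    defaults.update(kwargs)
    return BiblioRecord(**defaults)


@pytest.fixture
def tiny_corpus():
    """Six hand-built records for counting and network oracles."""
    return Corpus(records=[
        make_record("r1", authors=["A", "B"], countries=["Brazil"], year=2005),
        make_record("r2", authors=["A", "B"], countries=["Brazil", "Peru"], year=2006),
        make_record("r3", authors=["A", "C"], countries=["Peru"], year=2015),
        make_record("r4", authors=["C"], countries=["Spain"], year=2015),
        make_record("r5", authors=["B", "C", "D"], countries=["Brazil"], year=2020),
        make_record("r6", authors=["D"], countries=["France"], year=2020),
    ])


@pytest.fixture(scope="session")
def synth_default():
    """One default-parameter synthetic corpus, shared across tests."""
    return generate_corpus(SynthParams(seed=11))


@pytest.fixture(scope="session")
def synth_small():
    """A small, duplicate-free corpus for quick pipeline-level tests."""
    params = SynthParams(n_records=150, n_duplicates=0, n_name_variants=0, seed=7)
    return generate_corpus(params)
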