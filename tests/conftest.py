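import pytest

from timetriage.corpus import Corpus, Document
from timetriage.simulate import SimConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus() -> Corpus:
    """80 synthetic articles, strong figure-localized signal."""
    return generate_corpus(SimConfig(n_docs=80, seed=3, signal_boost=20.0))


@pytest.fixture(scope="session")
def medium_corpus() -> Corpus:
    """300 synthetic articles used by the heavier discovery/classification tests."""
    return generate_corpus(SimConfig(n_docs=300, seed=3, signal_boost=20.0))


def toy_labeled_corpus() -> Corpus:
    """Four tiny hand-countable documents, two per class."""
    return Corpus(
        [
            Document(id="p1", body="clade divergence clock", label="positive"),
            Document(id="p2", body="clade time tree", label="positive"),
            Document(id="n1", body="protein divergence assay", label="negative"),
            Document(id="n2", body="protein cell assay", label="negative"),
        ]
    )
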