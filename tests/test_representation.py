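"""TFIDF formula, embedding providers and representation enhancing."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from timetriage.corpus import Corpus, Document
from timetriage.embeddings import train_doc_embeddings, train_word_embeddings
from timetriage.representation import (
    HashingEmbeddingProvider,
    TfidfTextVectorizer,
    embed_corpus,
    enhanced_fit,
    tfidf_vectors,
)
from timetriage.simulate import SimConfig, generate_corpus


def corpus_of(*bodies, label=None):
    return Corpus([Document(id=f"d{i}", body=b, label=label) for i, b in enumerate(bodies)])


def test_term_in_every_document_has_unit_idf():
    vec = TfidfTextVectorizer().fit(["a b", "a c", "a d"])
    # "a" occurs in all N=3 documents: idf = ln((1+3)/(1+3)) + 1 = 1
    idf = vec.idf_[vec.vocabulary_.index("a")]
    assert idf == pytest.approx(1.0)


def test_single_document_hand_computation():
    dm = tfidf_vectors(corpus_of("a a b"))
    # tf(a)=2, tf(b)=1, idf both = ln(2/2)+1 = 1; L2 norm
    expected = np.array([2.0, 1.0]) / math.sqrt(5)
    np.testing.assert_allclose(dm.dense()[0], expected, atol=1e-12)


def test_rows_are_unit_or_zero_norm(medium_corpus):
    dm = tfidf_vectors(medium_corpus, min_df=2)
    norms = np.sqrt(np.asarray(dm.values.multiply(dm.values).sum(axis=1)).ravel())
    assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))


def test_fixed_vocabulary_gives_zero_row_for_unseen_tokens():
    train = corpus_of("clock divergence tree", "clock tree")
    vec = TfidfTextVectorizer().fit([d.body for d in train])
    fs = vec.feature_space()
    test = corpus_of("entirely novel words")
    dm = tfidf_vectors(test, fs=fs)
    assert dm.dense().sum() == 0.0
    assert dm.columns == fs.vocabulary


def test_hashing_provider_is_pure_and_shaped():
    provider = HashingEmbeddingProvider(dims=64)
    corpus = generate_corpus(SimConfig(n_docs=50, seed=2))
    a = embed_corpus(corpus, provider)
    b = embed_corpus(corpus, provider)
    assert a.shape == (50, 64)
    np.testing.assert_array_equal(a.dense(), b.dense())


def test_truncation_keeps_first_max_tokens():
    provider = HashingEmbeddingProvider(dims=32, max_tokens=512)
    long_doc = Corpus([Document(id="a", body=" ".join(f"w{i}" for i in range(10_000)))])
    head = Corpus([Document(id="a", body=" ".join(f"w{i}" for i in range(512)))])
    np.testing.assert_array_equal(
        embed_corpus(long_doc, provider).dense(), embed_corpus(head, provider).dense()
    )


def test_doc_embeddings_deterministic_and_zero_on_empty(medium_corpus):
    p1 = train_doc_embeddings(medium_corpus, dims=32, seed=1)
    p2 = train_doc_embeddings(medium_corpus, dims=32, seed=1)
    for d in list(medium_corpus)[:10]:
        np.testing.assert_array_equal(p1.embed(d.body), p2.embed(d.body))
    assert np.all(p1.embed("") == 0)
    assert p1.embed("x").shape == (32,)


def test_doc_embeddings_separate_disjoint_vocabularies():
    rng = np.random.default_rng(0)
    va = [f"alpha{i}" for i in range(15)]
    vb = [f"beta{i}" for i in range(15)]
    docs = []
    for i in range(30):
        words = rng.choice(va if i % 2 == 0 else vb, size=40)
        docs.append(Document(id=f"d{i}", body=" ".join(words)))
    corpus = Corpus(docs)
    provider = train_doc_embeddings(corpus, dims=8, min_count=2, seed=0)
    V = np.array([provider.embed(d.body) for d in corpus])
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    sims = V @ V.T
    same = [sims[i, j] for i in range(30) for j in range(30) if i < j and i % 2 == j % 2]
    diff = [sims[i, j] for i in range(30) for j in range(30) if i < j and i % 2 != j % 2]
    assert np.mean(same) > np.mean(diff)


def test_doc_embeddings_require_ten_documents():
    with pytest.raises(ValueError):
        train_doc_embeddings(corpus_of("a b c", "d e f"), dims=4)


def test_word_embedding_neighbors_respect_k(medium_corpus):
    we = train_word_embeddings(medium_corpus, dims=16, min_count=5, seed=0)
    word = next(iter(we.vocab))
    assert len(we.most_similar(word, k=10)) == 10


# --- representation enhancing --------------------------------------------

def test_empty_pool_equals_labeled_only_fit():
    labeled = corpus_of("clock tree", "divergence clade", label="positive")
    rep = enhanced_fit(labeled, Corpus([]), method="tfidf")
    solo = tfidf_vectors(labeled)
    dm = rep.labeled_matrix(labeled)
    assert dm.columns == solo.columns
    np.testing.assert_allclose(dm.dense(), solo.dense(), atol=1e-12)


def test_union_vocabulary_superset_and_row_alignment():
    labeled = corpus_of("clock tree", "divergence clade", label="positive")
    pool = Corpus([Document(id="u0", body="fossil calibration rates")])
    rep = enhanced_fit(labeled, pool, method="tfidf")
    solo = tfidf_vectors(labeled)
    assert set(rep.vectorizer.vocabulary_) >= set(solo.columns)
    dm = rep.labeled_matrix(labeled)
    assert dm.ids == labeled.ids()


def test_id_collision_between_pools_is_hard_error():
    labeled = corpus_of("a b", label="positive")
    pool = Corpus([Document(id="d0", body="c d")])
    with pytest.raises(ValueError, match="d0"):
        enhanced_fit(labeled, pool)
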