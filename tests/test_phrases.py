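"""Phrase discovery: TFIDF features, L1 selection, expansion, queries."""

import math
import re

import numpy as np
import pytest

from timetriage.corpus import Corpus, Document, tokenize
from timetriage.phrases import (
    build_feature_matrix,
    build_queries,
    discover_phrases,
    expand_phrases,
    extract_positive_phrases,
    frequency_scatter,
)
from timetriage.simulate import SimConfig, generate_corpus

from conftest import toy_labeled_corpus


def labeled(pairs):
    return Corpus(
        [Document(id=f"d{i}", body=b, label=l) for i, (b, l) in enumerate(pairs)]
    )


# --- feature matrix -------------------------------------------------------

def test_identical_one_word_documents_give_symmetric_matrix():
    corpus = labeled([("clock", "positive"), ("clock", "negative")])
    fs, X = build_feature_matrix(corpus, min_df=1)
    assert fs.vocabulary == ["clock"]
    dense = X.dense()
    assert dense.shape == (2, 1)
    assert dense[0, 0] == dense[1, 0] == 1.0  # L2-normalized single feature


def test_three_document_toy_matches_hand_computed_tfidf():
    corpus = labeled([("a b", "positive"), ("a c", "negative"), ("a", "negative")])
    fs, X = build_feature_matrix(corpus, min_df=1)

    # independent hand computation under the pinned formula
    docs = [["a", "b", "a b"], ["a", "c", "a c"], ["a"]]
    vocab = sorted({t for d in docs for t in d})
    n = len(docs)
    df = {t: sum(t in d for d in docs) for t in vocab}
    expected = []
    for d in docs:
        row = np.array(
            [d.count(t) * (math.log((1 + n) / (1 + df[t])) + 1) for t in vocab]
        )
        norm = np.linalg.norm(row)
        expected.append(row / norm if norm else row)
    assert fs.vocabulary == vocab
    np.testing.assert_allclose(X.dense(), np.vstack(expected), atol=1e-12)


def test_documents_contribute_word_pair_features():
    corpus = labeled(
        [("molecular clock analysis", "positive"), ("other text", "negative")]
    )
    fs, _ = build_feature_matrix(corpus, min_df=1)
    assert "molecular clock" in fs.vocabulary
    assert "clock analysis" in fs.vocabulary


def test_min_df_too_high_is_a_hard_error():
    corpus = labeled([("a b", "positive"), ("c d", "negative")])
    with pytest.raises(ValueError, match="min_df"):
        build_feature_matrix(corpus, min_df=3)


# --- L1 phrase selection --------------------------------------------------

def point_biserial_ranking(X, labels):
    """Independent oracle: features ranked by correlation with the label."""
    y = np.array([1.0 if l == "positive" else 0.0 for l in labels])
    M = X.dense()
    yc = y - y.mean()
    Mc = M - M.mean(axis=0)
    denom = np.linalg.norm(Mc, axis=0) * np.linalg.norm(yc)
    corr = np.where(denom > 0, (Mc.T @ yc) / np.where(denom == 0, 1, denom), 0.0)
    order = np.argsort(-corr, kind="stable")
    return [X.columns[j] for j in order]


def test_strongest_planted_phrase_ranks_in_pl_top5():
    corpus = generate_corpus(SimConfig(n_docs=400, seed=3, signal_boost=20.0))
    fs, X = build_feature_matrix(corpus, min_df=2)
    pl = extract_positive_phrases(X, corpus.labels(), seed=0)
    top5 = [p for p, _ in pl[:5]]
    # oracle: rank the planted signal phrases by point-biserial correlation;
    # the strongest must appear in PL's top five coefficients
    ranking = point_biserial_ranking(X, corpus.labels())
    planted = [p for p in ranking if p in SimConfig().signal_phrases]
    assert planted[0] in top5


def test_identical_documents_across_classes_give_empty_pl():
    corpus = labeled(
        [("same words here", "positive")] * 6 + [("same words here", "negative")] * 6
    )
    fs, X = build_feature_matrix(corpus, min_df=1)
    pl = extract_positive_phrases(X, corpus.labels(), cv_folds=3, seed=0)
    assert pl == []


def test_pl_set_invariant_under_dataset_duplication():
    corpus = generate_corpus(SimConfig(n_docs=120, seed=6, signal_boost=15.0))
    fs, X = build_feature_matrix(corpus, min_df=2)
    labels = corpus.labels()
    pl_once = extract_positive_phrases(X, labels, reg_strength_grid=[1.0], seed=0)

    from timetriage.representation import DocMatrix
    import scipy.sparse as sp

    X2 = DocMatrix(
        [f"{i}-{k}" for k in (0, 1) for i in X.ids],
        X.columns,
        sp.vstack([X.values, X.values]),
    )
    pl_twice = extract_positive_phrases(X2, labels * 2, reg_strength_grid=[1.0], seed=0)
    assert {p for p, _ in pl_once} == {p for p, _ in pl_twice}


def test_stronger_regularization_never_grows_pl():
    corpus = generate_corpus(SimConfig(n_docs=150, seed=4, signal_boost=15.0))
    fs, X = build_feature_matrix(corpus, min_df=2)
    sizes = [
        len(extract_positive_phrases(X, corpus.labels(), reg_strength_grid=[C], seed=0))
        for C in (0.01, 0.1, 1.0, 10.0)
    ]
    assert sizes == sorted(sizes)  # |pl| non-decreasing with weaker penalty


def test_single_class_labels_hard_error():
    corpus = labeled([("a b", "positive"), ("a c", "positive")])
    with pytest.raises(ValueError):
        fs, X = build_feature_matrix(corpus, min_df=1)


# --- embedding expansion --------------------------------------------------

def _adjacency_corpus():
    """'foo bar' always adjacent, inside sentences with a signature context
    vocabulary distinct from the general filler — so foo and bar share
    second-order contexts as well as first-order adjacency."""
    rng = np.random.default_rng(0)
    filler = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"]
    ctx = ["calib", "fossil"]
    docs = []
    for i in range(40):
        plain = " ".join(rng.choice(filler, size=12))
        signature = list(rng.choice(ctx, size=6))
        pos = int(rng.integers(0, len(signature)))
        signature[pos:pos] = ["foo", "bar"]  # always adjacent
        body = plain + ". " + " ".join(signature) + "."
        docs.append(Document(id=f"d{i}", body=body,
                             label="positive" if i % 3 else "negative"))
    return Corpus(docs)


def ppmi_neighbor_rank(corpus, target, window=5):
    """Independent oracle: cosine similarity on raw PPMI co-occurrence rows."""
    texts = [tokenize(d.body) for d in corpus]
    vocab = sorted({t for ts in texts for t in ts})
    idx = {w: i for i, w in enumerate(vocab)}
    C = np.zeros((len(vocab), len(vocab)))
    for ts in texts:
        for i, w in enumerate(ts):
            for j in range(max(0, i - window), min(len(ts), i + window + 1)):
                if j != i:
                    C[idx[w], idx[ts[j]]] += 1
    total = C.sum()
    row = C.sum(axis=1, keepdims=True)
    col = C.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(C * total / (row * col))
    P = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    t = P[idx[target]]
    sims = P @ t / (np.linalg.norm(P, axis=1) * np.linalg.norm(t) + 1e-12)
    order = np.argsort(-sims)
    return [vocab[i] for i in order if vocab[i] != target]


def test_adjacent_tokens_are_mutual_neighbors():
    corpus = _adjacency_corpus()
    wl = expand_phrases(corpus, ["foo"], k_neighbors=10, dims=8, min_count=2, seed=0)
    words = [w for w, _ in wl]
    assert "bar" in words
    assert "bar" in ppmi_neighbor_rank(corpus, "foo")[:3]  # oracle agrees


def test_neighbor_count_capped_at_k():
    corpus = _adjacency_corpus()
    wl = expand_phrases(corpus, ["foo"], k_neighbors=3, dims=8, min_count=1, seed=0)
    assert len(wl) <= 3


def test_empty_pl_yields_empty_wl(small_corpus):
    with pytest.warns(UserWarning):
        assert expand_phrases(small_corpus, [], seed=0) == []


def test_fl_is_union_and_wl_disjoint_from_pl():
    corpus = generate_corpus(SimConfig(n_docs=200, seed=3, signal_boost=15.0))
    p = discover_phrases(corpus, min_df=2, min_count=5, seed=0)
    pl_phrases = {w for w, _ in p.pl}
    wl_phrases = {w for w, _ in p.wl}
    assert pl_phrases.isdisjoint(wl_phrases)
    assert set(p.fl) == pl_phrases | wl_phrases
    assert all(c > 0 for _, c in p.pl)


# --- queries --------------------------------------------------------------

def _parse_boolean(query):
    """Tiny recursive-descent boolean grammar: oracle for query rendering."""
    tokens = re.findall(r'\(|\)|AND|OR|"[^"]*"', query)
    pos = 0

    def expect(tok):
        nonlocal pos
        assert pos < len(tokens) and tokens[pos] == tok, (tokens, pos)
        pos += 1

    def atom():
        nonlocal pos
        if tokens[pos] == "(":
            expect("(")
            expr()
            expect(")")
        else:
            assert tokens[pos].startswith('"')
            pos += 1

    def expr():
        nonlocal pos
        atom()
        while pos < len(tokens) and tokens[pos] in ("AND", "OR"):
            pos += 1
            atom()

    expr()
    assert pos == len(tokens)


def test_single_phrase_gives_one_quoted_simple_query():
    qs = build_queries(["molecular timetree"], complex_arity=2)
    assert len(qs) == 1
    assert qs[0].kind == "fl_simple"
    assert qs[0].text == '"molecular timetree"'


def test_three_phrases_arity_three_counts():
    qs = build_queries(["a", "b", "c"], complex_arity=3)
    kinds = [q.kind for q in qs]
    assert kinds.count("fl_simple") == 3
    assert kinds.count("fl_complex") == 1


def test_complex_queries_parse_under_boolean_grammar():
    qs = build_queries([f"phrase {i}" for i in range(7)], complex_arity=3)
    for q in qs:
        _parse_boolean(q.text)


def test_arity_exceeding_fl_warns_and_emits_simple_only():
    with pytest.warns(UserWarning):
        qs = build_queries(["only one", "two"], complex_arity=5)
    assert all(q.kind == "fl_simple" for q in qs)


# --- frequency scatter ----------------------------------------------------

def test_class_exclusive_word_has_zero_other_frequency():
    table = frequency_scatter(toy_labeled_corpus())
    row = table[table.word == "clade"].iloc[0]
    assert row.freq_in_negatives == 0.0
    assert row.freq_in_positives > 0.0


def test_per_class_frequencies_sum_to_one():
    table = frequency_scatter(toy_labeled_corpus())
    assert table.freq_in_positives.sum() == pytest.approx(1.0, abs=1e-9)
    assert table.freq_in_negatives.sum() == pytest.approx(1.0, abs=1e-9)


def test_toy_corpus_matches_hand_count():
    table = frequency_scatter(toy_labeled_corpus()).set_index("word")
    # positives: clade x2, divergence, clock, time, tree (6 tokens)
    assert table.loc["clade", "freq_in_positives"] == pytest.approx(2 / 6)
    # negatives: protein x2, divergence, assay x2, cell (6 tokens)
    assert table.loc["protein", "freq_in_negatives"] == pytest.approx(2 / 6)
    assert table.loc["divergence", "freq_in_negatives"] == pytest.approx(1 / 6)


def test_unlabeled_corpus_is_hard_error():
    corpus = Corpus([Document(id="a", body="x y z")])
    with pytest.raises(ValueError):
        frequency_scatter(corpus)
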