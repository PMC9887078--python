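"""Deterministic word and document embeddings trained from a corpus.

Word vectors are obtained by factorizing a positive pointwise-mutual-
information (PPMI) weighted co-occurrence matrix with a truncated SVD — the
closed-form counterpart of skip-gram with negative sampling, sharing its
hyperparameters (symmetric context window, embedding dimensionality, minimum
token count).  The factorization route is exactly reproducible on one CPU:
the same corpus, window, dimensionality and seed always yield the same
vectors, which stochastic-gradient word2vec training cannot guarantee.

Document embeddings are idf-weighted averages of the word vectors, a strong
deterministic baseline for paragraph-vector models: inference on new text
needs only the stored vocabulary, idf table and word matrix, and embedding
empty text is defined as the all-zero vector.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from .corpus import Corpus, tokenize

__all__ = ["WordEmbeddings", "train_word_embeddings", "DocEmbeddingProvider", "train_doc_embeddings"]


def _cooccurrence(
    token_lists: list[list[str]], vocab: dict[str, int], window: int
) -> sp.csr_matrix:
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for tokens in token_lists:
        idx = [vocab.get(t, -1) for t in tokens]
        n = len(idx)
        for i, wi in enumerate(idx):
            if wi < 0:
                continue
            for j in range(max(0, i - window), min(n, i + window + 1)):
                if j == i:
                    continue
                wj = idx[j]
                if wj < 0:
                    continue
                rows.append(wi)
                cols.append(wj)
                vals.append(1.0)
    v = len(vocab)
    return sp.coo_matrix((vals, (rows, cols)), shape=(v, v)).tocsr()


def _ppmi(counts: sp.csr_matrix) -> sp.csr_matrix:
    total = counts.sum()
    if total == 0:
        return counts
    row = np.asarray(counts.sum(axis=1)).ravel()
    col = np.asarray(counts.sum(axis=0)).ravel()
    coo = counts.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(coo.data * total / (row[coo.row] * col[coo.col]))
    keep = pmi > 0
    return sp.coo_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=counts.shape
    ).tocsr()


@dataclass
class WordEmbeddings:
    """Fixed word vectors with cosine nearest-neighbor lookup."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (n_vocab, dims), rows L2-normalized
    counts: dict[str, int]
    dims: int
    window: int

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocab[word]]

    def most_similar(self, word: str, k: int = 10) -> list[tuple[str, float]]:
        """The ``k`` nearest vocabulary words by cosine similarity."""
        if word not in self.vocab:
            raise KeyError(word)
        sims = self.vectors @ self.vector(word)
        order = np.argsort(-sims, kind="stable")
        words = list(self.vocab)
        out = []
        for i in order:
            if words[i] == word:
                continue
            out.append((words[i], float(sims[i])))
            if len(out) == k:
                break
        return out


def train_word_embeddings(
    corpus: Corpus,
    dims: int = 100,
    window: int = 5,
    min_count: int = 5,
    seed: int = 0,
) -> WordEmbeddings:
    """Train PPMI-SVD word vectors on the corpus token stream."""
    token_lists = [tokenize(doc.text()) for doc in corpus]
    counts = Counter(t for toks in token_lists for t in toks)
    words = sorted(w for w, c in counts.items() if c >= min_count)
    if len(words) < 2:
        raise ValueError("corpus vocabulary too small to train embeddings")
    vocab = {w: i for i, w in enumerate(words)}

    ppmi = _ppmi(_cooccurrence(token_lists, vocab, window))
    k = min(dims, len(words) - 1)
    svd = TruncatedSVD(n_components=k, algorithm="arpack", random_state=seed)
    vecs = svd.fit_transform(ppmi)
    # fix sign per component so the decomposition is unique up to tolerance
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if k < dims:
        vecs = np.hstack([vecs, np.zeros((vecs.shape[0], dims - k))])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return WordEmbeddings(
        vocab=vocab,
        vectors=vecs / norms,
        counts={w: counts[w] for w in words},
        dims=dims,
        window=window,
    )


@dataclass
class DocEmbeddingProvider:
    """Document embedding provider: idf-weighted mean of trained word vectors.

    Satisfies the embedding-provider contract: ``embed`` is a pure function
    of the input text, output length is ``dims``, and ``embed("")`` is the
    zero vector.  ``max_tokens`` is None (no truncation limit of its own).
    """

    word_embeddings: WordEmbeddings
    idf: dict[str, float]
    dims: int
    name: str = "doc-ppmi-svd"
    max_tokens: int | None = None

    def embed(self, text: str) -> np.ndarray:
        tokens = tokenize(text)
        acc = np.zeros(self.dims)
        weight = 0.0
        we = self.word_embeddings
        for t in tokens:
            if t in we.vocab:
                w = self.idf.get(t, 1.0)
                acc += w * we.vector(t)
                weight += w
        if weight > 0:
            acc /= weight
        return acc


def train_doc_embeddings(
    corpus: Corpus,
    dims: int = 100,
    epochs: int = 1,
    seed: int = 0,
    window: int = 5,
    min_count: int = 5,
) -> DocEmbeddingProvider:
    """Fit a deterministic document-embedding provider on the corpus.

    ``epochs`` is accepted for interface compatibility with iterative
    trainers; the factorization route converges in one pass.
    """
    if len(corpus) < 10:
        raise ValueError("need at least 10 documents to train document embeddings")
    we = train_word_embeddings(corpus, dims=dims, window=window, min_count=min_count, seed=seed)
    n = len(corpus)
    df = Counter()
    for doc in corpus:
        df.update(set(tokenize(doc.text())))
    idf = {
        w: math.log((1 + n) / (1 + df[w])) + 1.0 for w in we.vocab
    }
    return DocEmbeddingProvider(word_embeddings=we, idf=idf, dims=dims)
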