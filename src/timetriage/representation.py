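"""Document representations: TFIDF vectors and embedding providers.

TFIDF uses one pinned formula throughout the package: raw term count tf,
smoothed idf ``ln((1+N)/(1+df)) + 1`` with N the corpus size, value
``tf * idf``, rows L2-normalized (an all-zero row stays zero).  Vocabularies
fitted on a training corpus can be re-applied to new corpora so train and
test matrices share one feature space; out-of-vocabulary tokens are ignored.

Embedding providers abstract contextual or paragraph embeddings behind one
contract: a ``dims``-length deterministic vector per text, with optional
truncation to the first ``max_tokens`` tokens for providers with a bounded
input length.  The shipped :class:`HashingEmbeddingProvider` feature-hashes
token n-grams to ``dims`` buckets — a pure function of the text — so the
full pipeline is exercisable without any pretrained weights; trained
document embeddings (see :mod:`timetriage.embeddings`) satisfy the same
contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Corpus, ngrams, tokenize

__all__ = [
    "DocMatrix",
    "FeatureSpace",
    "EmbeddingProvider",
    "HashingEmbeddingProvider",
    "TfidfTextVectorizer",
    "tfidf_vectors",
    "embed_corpus",
    "enhanced_fit",
    "EnhancedRepresentation",
]


@dataclass
class FeatureSpace:
    """A fitted vocabulary: ordered features with document frequencies."""

    vocabulary: list[str]
    doc_freq: np.ndarray
    min_df: int
    ngram_range: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if sorted(set(self.vocabulary)) != list(self.vocabulary):
            raise ValueError("vocabulary must be sorted and duplicate-free")


@dataclass
class DocMatrix:
    """Documents-by-features matrix with aligned ids and column names."""

    ids: list[str]
    columns: list[str]
    values: "np.ndarray | sp.spmatrix"

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.ids):
            raise ValueError(f"row count {n} != number of ids {len(self.ids)}")
        if m != len(self.columns):
            raise ValueError(f"column count {m} != number of columns {len(self.columns)}")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def rows(self, ids: Sequence[str]) -> "DocMatrix":
        index = {d: i for i, d in enumerate(self.ids)}
        sel = [index[d] for d in ids]
        return DocMatrix(list(ids), self.columns, self.values[sel])


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for text-embedding backends."""

    name: str
    dims: int
    max_tokens: int | None

    def embed(self, text: str) -> np.ndarray: ...


def _analyzer_for(ngram_range: tuple[int, int]):
    lo, hi = ngram_range

    def analyze(text: str) -> list[str]:
        return ngrams(tokenize(text), lo, hi)

    return analyze


class TfidfTextVectorizer(TransformerMixin, BaseEstimator):
    """TFIDF vectorizer over raw texts with the package's shared tokenizer.

    sklearn-style estimator: ``fit`` learns the vocabulary (optionally pinned
    via ``vocabulary``), ``transform`` maps texts to L2-normalized TFIDF rows.
    Fitted attributes: ``vocabulary_`` (sorted feature list), ``doc_freq_``.
    """

    def __init__(self, ngram_range: tuple[int, int] = (1, 1), min_df: int = 1,
                 vocabulary: Sequence[str] | None = None):
        self.ngram_range = ngram_range
        self.min_df = min_df
        self.vocabulary = vocabulary

    def fit(self, texts: Sequence[str], y=None) -> "TfidfTextVectorizer":
        vocab = sorted(self.vocabulary) if self.vocabulary is not None else None
        self._tfidf = TfidfVectorizer(
            analyzer=_analyzer_for(self.ngram_range),
            min_df=self.min_df,
            vocabulary=vocab,
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        try:
            self._tfidf.fit(texts)
        except ValueError as exc:
            raise ValueError(
                f"empty vocabulary after min_df={self.min_df}; lower min_df"
            ) from exc
        self.vocabulary_ = sorted(self._tfidf.vocabulary_, key=self._tfidf.vocabulary_.get)
        X = self._tfidf.transform(texts)
        self.doc_freq_ = np.asarray((X != 0).sum(axis=0)).ravel().astype(int)
        self.idf_ = self._tfidf.idf_
        self.n_docs_ = len(texts)
        return self

    def transform(self, texts: Sequence[str]) -> sp.csr_matrix:
        return self._tfidf.transform(texts)

    def feature_space(self) -> FeatureSpace:
        return FeatureSpace(
            vocabulary=list(self.vocabulary_),
            doc_freq=self.doc_freq_,
            min_df=self.min_df,
            ngram_range=self.ngram_range,
        )


def tfidf_vectors(
    corpus: Corpus,
    fs: FeatureSpace | None = None,
    ngram_range: tuple[int, int] = (1, 1),
    min_df: int = 1,
) -> DocMatrix:
    """TFIDF matrix for a corpus under the pinned formula.

    When a fitted :class:`FeatureSpace` is given, its vocabulary (and ngram
    order) is reused and out-of-vocabulary tokens are ignored, so train and
    test matrices align column-for-column.
    """
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    texts = [doc.text() for doc in corpus]
    if fs is not None:
        vec = TfidfTextVectorizer(ngram_range=fs.ngram_range, min_df=1,
                                  vocabulary=fs.vocabulary)
    else:
        vec = TfidfTextVectorizer(ngram_range=ngram_range, min_df=min_df)
    X = vec.fit(texts).transform(texts)
    return DocMatrix(corpus.ids(), list(vec.vocabulary_), X)


@dataclass
class HashingEmbeddingProvider:
    """Deterministic mock embedding backend: feature-hashed token n-grams.

    Each unigram and bigram is hashed (BLAKE2b) to a bucket in ``dims`` with
    a hash-derived sign; the bucket-count vector is L2-normalized.  Identical
    text always embeds identically, making the provider a drop-in stand-in
    for contextual-embedding backends in tests and offline runs.
    """

    dims: int = 64
    max_tokens: int | None = 512
    name: str = "hashing-mock"

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dims)
        tokens = tokenize(text)
        if self.max_tokens is not None:
            tokens = tokens[: self.max_tokens]
        for gram in ngrams(tokens, 1, 2):
            h = int.from_bytes(
                hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest(), "big"
            )
            idx = h % self.dims
            sign = 1.0 if (h >> 32) & 1 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def embed_corpus(corpus: Corpus, provider: EmbeddingProvider) -> DocMatrix:
    """Embed every document with a provider; rows follow corpus order.

    Text is truncated to the provider's first ``max_tokens`` tokens (bounded-
    input backends look only at the beginning of an article).
    """
    rows = []
    for doc in corpus:
        text = doc.text()
        if provider.max_tokens is not None:
            text = " ".join(tokenize(text)[: provider.max_tokens])
        try:
            v = provider.embed(text)
        except Exception as exc:  # pragma: no cover - provider contract breach
            raise RuntimeError(f"embedding failed for document {doc.id!r}: {exc}") from exc
        if len(v) != provider.dims:
            raise RuntimeError(
                f"provider {provider.name!r} returned {len(v)} dims for "
                f"document {doc.id!r}; expected {provider.dims}"
            )
        rows.append(np.asarray(v, dtype=float))
    values = np.vstack(rows) if rows else np.zeros((0, provider.dims))
    return DocMatrix(corpus.ids(), [str(j) for j in range(provider.dims)], values)


@dataclass
class EnhancedRepresentation:
    """Representation fitted on labeled + unlabeled pools.

    The vocabulary or embedding model sees the union of both corpora (labels
    play no role in representation learning); classification later uses the
    labeled rows only, via :meth:`labeled_matrix`.
    """

    method: str
    labeled_ids: list[str]
    vectorizer: TfidfTextVectorizer | None = None
    provider: "EmbeddingProvider | None" = None

    def transform(self, corpus: Corpus) -> DocMatrix:
        if self.method == "tfidf":
            X = self.vectorizer.transform([d.text() for d in corpus])
            return DocMatrix(corpus.ids(), list(self.vectorizer.vocabulary_), X)
        return embed_corpus(corpus, self.provider)

    def labeled_matrix(self, labeled: Corpus) -> DocMatrix:
        return self.transform(labeled)


def enhanced_fit(
    labeled: Corpus,
    unlabeled_pool: Corpus,
    method: str = "tfidf",
    ngram_range: tuple[int, int] = (1, 1),
    min_df: int = 1,
    dims: int = 100,
    seed: int = 0,
) -> EnhancedRepresentation:
    """Fit a representation on the union of labeled and unlabeled corpora."""
    overlap = set(labeled.ids()) & set(unlabeled_pool.ids())
    if overlap:
        raise ValueError(f"labeled and unlabeled ids overlap: {sorted(overlap)[:5]}")
    union = Corpus(list(labeled) + list(unlabeled_pool), "enhanced-union")
    if method == "tfidf":
        vec = TfidfTextVectorizer(ngram_range=ngram_range, min_df=min_df)
        vec.fit([d.text() for d in union])
        return EnhancedRepresentation("tfidf", labeled.ids(), vectorizer=vec)
    if method == "doc_embeddings":
        from .embeddings import train_doc_embeddings

        provider = train_doc_embeddings(union, dims=dims, seed=seed)
        return EnhancedRepresentation("doc_embeddings", labeled.ids(), provider=provider)
    raise ValueError(f"unknown representation method {method!r}")
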