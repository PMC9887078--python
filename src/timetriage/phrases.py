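"""Discriminative-phrase discovery and search-query construction.

From a labeled corpus, build unigram+bigram TFIDF features, fit an
L1-regularized logistic regression (regularization strength chosen by
F1-maximizing cross-validation), and keep the features with strictly
positive coefficients: the phrase list PL, ranked by coefficient.  Each PL
unigram is then expanded with its nearest neighbors in a word-embedding
space trained on the same corpus; pooled neighbors are frequency-filtered
(dropping rare words and misspellings) to give the expansion list WL.  The
final list FL is the union of PL and WL phrases and feeds two query shapes:
one quoted phrase per query (simple), or a boolean combination of a phrase
group (complex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .corpus import Corpus, tokenize
from .embeddings import train_word_embeddings
from .representation import DocMatrix, FeatureSpace, TfidfTextVectorizer
from .stopwords import stopword_set

__all__ = [
    "PhraseList",
    "Query",
    "build_feature_matrix",
    "extract_positive_phrases",
    "expand_phrases",
    "discover_phrases",
    "build_queries",
    "frequency_scatter",
    "L1PhraseSelector",
]

DEFAULT_REG_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class PhraseList:
    """PL (phrase, coefficient), WL (word, similarity) and their union FL."""

    pl: list[tuple[str, float]] = field(default_factory=list)
    wl: list[tuple[str, float]] = field(default_factory=list)

    @property
    def fl(self) -> list[str]:
        pl_phrases = [p for p, _ in self.pl]
        return pl_phrases + [w for w, _ in self.wl if w not in set(pl_phrases)]

    def to_dict(self) -> dict:
        return {
            "pl": [{"phrase": p, "coef": c} for p, c in self.pl],
            "wl": [{"phrase": w, "sim": s} for w, s in self.wl],
            "fl": self.fl,
        }


@dataclass(frozen=True)
class Query:
    """A rendered search query over FL phrases."""

    kind: str  # 'fl_simple' | 'fl_complex'
    text: str
    phrases: tuple[str, ...]


def build_feature_matrix(
    corpus: Corpus, min_df: int = 1
) -> tuple[FeatureSpace, DocMatrix]:
    """Unigram+bigram TFIDF features from a labeled corpus."""
    if len(corpus) < 2:
        raise ValueError("need at least 2 documents")
    labels = set(corpus.labels())
    if not {"positive", "negative"} <= labels:
        raise ValueError("corpus must contain both positive and negative labels")
    texts = [doc.text() for doc in corpus]
    vec = TfidfTextVectorizer(ngram_range=(1, 2), min_df=min_df)
    X = vec.fit(texts).transform(texts)
    return vec.feature_space(), DocMatrix(corpus.ids(), list(vec.vocabulary_), X)


class L1PhraseSelector(BaseEstimator):
    """L1-logistic-regression feature selector, sklearn-style.

    ``fit(X, y)`` selects the regularization strength from ``reg_grid`` by
    mean F1 over stratified ``cv_folds``-fold CV (ties go to the first grid
    entry), refits on all rows, and exposes ``phrases_``: features with
    strictly positive coefficient, sorted by coefficient descending.

    Grid strengths are calibrated to a reference corpus of ``N_REF`` documents
    and the effective penalty scales with 1/n_samples, so the penalized
    objective — and hence the selected feature set — is invariant under exact
    dataset duplication.
    """

    N_REF = 256

    def __init__(
        self,
        feature_names: Sequence[str] | None = None,
        reg_grid: Sequence[float] = DEFAULT_REG_GRID,
        cv_folds: int = 5,
        seed: int = 0,
    ):
        self.feature_names = feature_names
        self.reg_grid = reg_grid
        self.cv_folds = cv_folds
        self.seed = seed

    @classmethod
    def _model(cls, C: float, n: int, seed: int) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=1.0, C=C * cls.N_REF / n, solver="liblinear",
            random_state=seed, max_iter=5000, tol=1e-8,
        )

    def fit(self, X, y) -> "L1PhraseSelector":
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("labels must contain both classes")
        n = X.shape[0]
        cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
        scores = []
        pos_label = "positive" if "positive" in classes else classes[-1]
        for C in self.reg_grid:
            s = cross_val_score(
                self._model(C, n, self.seed), X, y, cv=cv,
                scoring=lambda est, Xv, yv: f1_score(
                    yv, est.predict(Xv), pos_label=pos_label, zero_division=0
                ),
            )
            scores.append(float(np.mean(s)))
        best = int(np.argmax(scores))  # ties -> first grid entry
        self.chosen_C_ = float(self.reg_grid[best])
        self.cv_f1_by_C_ = dict(zip(self.reg_grid, scores))
        model = self._model(self.chosen_C_, n, self.seed).fit(X, y)
        # coefficient sign convention: positive = pushes toward 'positive'
        pos_index = list(model.classes_).index(pos_label)
        coefs = model.coef_[0] if pos_index == 1 else -model.coef_[0]
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"f{j}" for j in range(X.shape[1])]
        )
        order = np.argsort(-coefs, kind="stable")
        self.phrases_ = [
            (names[j], float(coefs[j])) for j in order if coefs[j] > 0
        ]
        self.model_ = model
        return self


def extract_positive_phrases(
    X: DocMatrix,
    labels: Sequence[str],
    reg_strength_grid: Sequence[float] = DEFAULT_REG_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """PL: positively weighted features of the CV-selected L1 model."""
    sel = L1PhraseSelector(
        feature_names=X.columns, reg_grid=reg_strength_grid,
        cv_folds=cv_folds, seed=seed,
    )
    sel.fit(X.values, list(labels))
    return sel.phrases_


def expand_phrases(
    corpus: Corpus,
    pl: Sequence[tuple[str, float]] | Sequence[str],
    k_neighbors: int = 10,
    dims: int = 100,
    min_count: int = 5,
    window: int = 5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """WL: nearest embedding neighbors of PL unigrams, frequency-filtered.

    For each PL unigram present in the embedding vocabulary, take its
    ``k_neighbors`` nearest words by cosine similarity; pool, deduplicate
    (keeping each word's best similarity), drop words already in PL, and drop
    words occurring fewer than ``min_count`` times in the corpus (rare
    combinations and misspellings).
    """
    pl_phrases = [p[0] if isinstance(p, tuple) else p for p in pl]
    if not pl_phrases:
        warnings.warn("empty PL: returning empty expansion list")
        return []
    we = train_word_embeddings(
        corpus, dims=dims, window=window, min_count=min_count, seed=seed
    )
    pl_set = set(pl_phrases)
    best: dict[str, float] = {}
    for phrase in pl_phrases:
        if " " in phrase:
            continue  # expansion operates on unigrams only
        if phrase not in we:
            warnings.warn(f"PL word {phrase!r} absent from embedding vocabulary; skipped")
            continue
        for word, sim in we.most_similar(phrase, k=k_neighbors):
            if word in pl_set:
                continue
            if we.counts.get(word, 0) < min_count:
                continue
            if word not in best or sim > best[word]:
                best[word] = sim
    return sorted(best.items(), key=lambda ws: (-ws[1], ws[0]))


def discover_phrases(
    corpus: Corpus,
    min_df: int = 2,
    reg_strength_grid: Sequence[float] = DEFAULT_REG_GRID,
    k_neighbors: int = 10,
    dims: int = 100,
    min_count: int = 5,
    seed: int = 0,
) -> PhraseList:
    """End-to-end phrase discovery: features -> PL -> WL -> FL."""
    _, X = build_feature_matrix(corpus, min_df=min_df)
    pl = extract_positive_phrases(
        X, [d.label for d in corpus], reg_strength_grid, seed=seed
    )
    wl = expand_phrases(
        corpus, pl, k_neighbors=k_neighbors, dims=dims, min_count=min_count, seed=seed
    )
    return PhraseList(pl=pl, wl=wl)


def build_queries(fl: Sequence[str], complex_arity: int = 3) -> list[Query]:
    """Render FL phrases as search queries.

    One simple query per phrase (quoted verbatim), plus complex queries over
    consecutive groups of ``complex_arity`` phrases in FL order, rendered as
    ``("p1") AND ("p2" OR "p3" ...)``.  Deterministic given FL order.
    """
    if not fl:
        raise ValueError("FL must be non-empty")
    if complex_arity < 2:
        raise ValueError("complex_arity must be >= 2")
    queries = [Query("fl_simple", f'"{p}"', (p,)) for p in fl]
    if complex_arity > len(fl):
        warnings.warn("complex_arity exceeds |FL|; emitting simple queries only")
        return queries
    for i in range(0, len(fl) - complex_arity + 1, complex_arity):
        group = tuple(fl[i : i + complex_arity])
        rest = " OR ".join(f'"{p}"' for p in group[1:])
        queries.append(
            Query("fl_complex", f'("{group[0]}") AND ({rest})', group)
        )
    return queries


def frequency_scatter(
    corpus: Corpus, extra_stopwords: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-class relative word frequencies for scatter/cloud displays.

    Stop words removed; within each class, relative frequencies sum to 1.
    Columns: ``word``, ``freq_in_positives``, ``freq_in_negatives``.
    """
    if any(d.label is None for d in corpus):
        raise ValueError("frequency_scatter requires a fully labeled corpus")
    stops = stopword_set(extra_stopwords)
    counts = {"positive": {}, "negative": {}}
    for doc in corpus:
        c = counts[doc.label]
        for tok in tokenize(doc.text()):
            if tok in stops:
                continue
            c[tok] = c.get(tok, 0) + 1
    pos_total = sum(counts["positive"].values())
    neg_total = sum(counts["negative"].values())
    if pos_total == 0 or neg_total == 0:
        raise ValueError("both classes must contribute at least one counted token")
    words = sorted(set(counts["positive"]) | set(counts["negative"]))
    return pd.DataFrame(
        {
            "word": words,
            "freq_in_positives": [counts["positive"].get(w, 0) / pos_total for w in words],
            "freq_in_negatives": [counts["negative"].get(w, 0) / neg_total for w in words],
        }
    )
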