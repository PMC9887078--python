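"""Keyword filtering of bulk article corpora.

Bulk repositories are dominated by articles unrelated to phylogenetics; a
cheap first pass drops every article that contains none of a configured list
of timetree-relevant phrases.  The filter is designed to be recall-safe: any
article containing at least one phrase anywhere in title, abstract or body is
retained, so a well-chosen phrase list yields a zero false-negative rate while
discarding the bulk of irrelevant material.

Matching is at token boundaries on normalized text ("divergence" does not
match "divergences"); bigram phrases must match as adjacent tokens.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .corpus import Corpus, normalize_text, tokenize

__all__ = ["FilterList", "KeywordFilter", "apply_filter", "DEFAULT_FILTER_PHRASES"]

#: Default phrase list, seeded from the most common words of curated
#: timetree-article corpora; configuration, not ground truth.
DEFAULT_FILTER_PHRASES = (
    "species",
    "evolution",
    "molecular",
    "phylogenetic",
    "tree",
    "clade",
    "divergence",
    "timetree",
)


@dataclass(frozen=True)
class FilterList:
    """Lowercase phrase list (unigrams or bigrams) matched at token boundaries."""

    phrases: tuple[str, ...]
    match_mode: str = "token_boundary"

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError("filter phrase list must be non-empty")
        norm = tuple(" ".join(tokenize(p)) for p in self.phrases)
        if any(not p for p in norm):
            raise ValueError("filter phrases must contain at least one token")
        object.__setattr__(self, "phrases", norm)

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterList":
        """Read phrases from a plain-text file, one per line, '#' comments."""
        phrases = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                phrases.append(line)
        return cls(tuple(phrases))


def _matches(tokens: list[str], unigrams: set[str], bigrams: set[tuple[str, str]]) -> bool:
    if unigrams and not unigrams.isdisjoint(tokens):
        return True
    if bigrams:
        for a, b in zip(tokens, tokens[1:]):
            if (a, b) in bigrams:
                return True
    return False


class KeywordFilter:
    """Retain documents containing at least one phrase of a :class:`FilterList`."""

    def __init__(self, flt: FilterList):
        self.filter_list = flt
        parts = [p.split() for p in flt.phrases]
        self.unigrams_ = {p[0] for p in parts if len(p) == 1}
        self.bigrams_ = {(p[0], p[1]) for p in parts if len(p) == 2}
        longer = [p for p in parts if len(p) > 2]
        if longer:
            raise ValueError(
                f"filter phrases must be unigrams or bigrams; got {longer[0]}"
            )

    def matches(self, text: str) -> bool:
        return _matches(tokenize(normalize_text(text), normalized=True),
                        self.unigrams_, self.bigrams_)

    def transform(self, corpus: Corpus) -> tuple[Corpus, dict]:
        """Apply the filter; returns (retained corpus, count report).

        The report carries ``n_in``, ``n_retained``, ``n_removed`` and, when
        labels are present, per-label retention rates.
        """
        retained = [doc for doc in corpus if self.matches(doc.text())]
        report: dict = {
            "n_in": len(corpus),
            "n_retained": len(retained),
            "n_removed": len(corpus) - len(retained),
        }
        labels = [d.label for d in corpus if d.label is not None]
        if labels:
            kept_ids = {d.id for d in retained}
            for lab in sorted(set(labels)):
                total = sum(1 for d in corpus if d.label == lab)
                kept = sum(1 for d in corpus if d.label == lab and d.id in kept_ids)
                report[f"retention_{lab}"] = kept / total if total else 0.0
        return Corpus(retained, corpus.provenance), report


def apply_filter(corpus: Corpus, flt: FilterList) -> tuple[Corpus, dict]:
    """Functional form of :meth:`KeywordFilter.transform`."""
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    return KeywordFilter(flt).transform(corpus)
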