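"""Figure-mention detection and excerpt extraction from article bodies.

Timetrees are almost always presented as figures, so the text immediately
surrounding figure mentions — and figure captions themselves — carries most
of the evidence for whether an article contains one.  This module locates
every in-text figure reference ("Fig. 3", "Figure 2", supplementary
variants), classifies references that open a paragraph as captions (paragraph
boundaries are blank lines), and cuts character windows centered on each
mention: half the window before the mention start, half after, clipped at
document bounds.  Caption paragraphs are taken whole regardless of window
size.  Overlapping or adjacent windows are merged, so an excerpt document is
a sorted list of disjoint spans plus their concatenated text.

All offsets are on the normalized body (CRLF folded, horizontal whitespace
collapsed), so excerpt spans are reproducible across platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus import Corpus, Document, normalize_text

__all__ = [
    "FigureMention",
    "ExcerptDoc",
    "FIGURE_MENTION_RE",
    "find_figure_mentions",
    "extract_excerpts",
    "excerpt_corpus",
    "paragraph_spans",
]

# Figure-token grammar: optional supplementary marker, then "figure(s)" or the
# abbreviation "fig(s)" (which requires a following dot or whitespace), then an
# optional figure number.
FIGURE_MENTION_RE = re.compile(
    r"\b(?:(?P<supp>supplementary|suppl\.?|s)\s+)?"
    r"(?:(?P<word>figures?)\b|(?P<abbr>figs?)(?:\.|(?=\s)))"
    r"(?:\s*(?P<num>\d+))?",
    re.IGNORECASE,
)

_BLANK_LINE_RE = re.compile(r"\n[ \t]*\n")


@dataclass(frozen=True)
class FigureMention:
    """One in-text figure reference, located by character offset in the body."""

    doc_id: str
    char_offset: int
    mention_text: str
    is_caption: bool
    is_supplementary: bool


@dataclass
class ExcerptDoc:
    """Disjoint character spans of one document plus their joined text."""

    doc_id: str
    spans: list[tuple[int, int]]
    text: str
    window: int
    label: str | None = None


def paragraph_spans(body: str) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of paragraphs: maximal runs of non-blank
    lines delimited by blank lines."""
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _BLANK_LINE_RE.finditer(body):
        if m.start() > pos:
            spans.append((pos, m.start()))
        pos = m.end()
    if pos < len(body):
        spans.append((pos, len(body)))
    # trim leading/trailing whitespace inside each paragraph span
    out = []
    for s, e in spans:
        seg = body[s:e]
        ls = len(seg) - len(seg.lstrip())
        rs = len(seg) - len(seg.rstrip())
        if s + ls < e - rs:
            out.append((s + ls, e - rs))
    return out


def find_figure_mentions(doc: Document, *, pre_normalized: bool = False) -> list[FigureMention]:
    """Locate every figure-token match in the document body.

    A mention is a caption when it starts a paragraph; it is supplementary
    when preceded by a supplementary marker.  Offsets refer to the normalized
    body (pass ``pre_normalized=True`` if ``doc.body`` is already normalized).
    """
    body = doc.body if pre_normalized else normalize_text(doc.body)
    par_starts = {s for s, _ in paragraph_spans(body)}
    mentions: list[FigureMention] = []
    for m in FIGURE_MENTION_RE.finditer(body):
        mentions.append(
            FigureMention(
                doc_id=doc.id,
                char_offset=m.start(),
                mention_text=m.group(0),
                is_caption=m.start() in par_starts,
                is_supplementary=m.group("supp") is not None,
            )
        )
    return mentions


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s <= pe:  # overlapping or adjacent
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def extract_excerpts(doc: Document, window: int, *, separator: str = "\n") -> ExcerptDoc:
    """Cut excerpt spans of ``window`` characters around each figure mention.

    Non-caption mentions yield ``[offset - window//2, offset - window//2 +
    window)`` clipped to the body; caption mentions yield their whole caption
    paragraph.  Spans are merged when overlapping or adjacent.  A document
    with no mentions yields empty spans and empty text.
    """
    if window < 50:
        raise ValueError("window must be >= 50 characters")
    body = normalize_text(doc.body)
    mentions = find_figure_mentions(doc.with_(body=body), pre_normalized=True)
    pars = paragraph_spans(body)
    intervals: list[tuple[int, int]] = []
    for m in mentions:
        if m.is_caption:
            for s, e in pars:
                if s <= m.char_offset < e:
                    intervals.append((s, e))
                    break
        else:
            # clip at document start by shifting (the full window is kept
            # when possible); the end clips at the document boundary
            start = max(0, m.char_offset - window // 2)
            intervals.append((start, min(len(body), start + window)))
    spans = _merge(intervals)
    text = separator.join(body[s:e] for s, e in spans)
    return ExcerptDoc(doc_id=doc.id, spans=spans, text=text, window=window, label=doc.label)


def excerpt_corpus(corpus: Corpus, window: int) -> tuple[Corpus, dict]:
    """Replace every document body by its excerpt text.

    Labels, year and id are preserved; ``source`` is retagged
    ``excerpt:<window>``.  Documents without a single figure mention keep an
    empty body and are listed in the returned report rather than dropped, so
    they stay auditable.
    """
    docs = []
    no_mention: list[str] = []
    for doc in corpus:
        exc = extract_excerpts(doc, window)
        if not exc.spans:
            no_mention.append(doc.id)
        docs.append(doc.with_(body=exc.text, source=f"excerpt:{window}"))
    report = {"n_docs": len(corpus), "n_no_mention": len(no_mention), "no_mention_ids": no_mention}
    return Corpus(docs, provenance=f"{corpus.provenance}|excerpt:{window}"), report
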