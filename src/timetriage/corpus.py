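"""Article corpus containers, JSONL/text-directory IO and shared text handling.

A :class:`Document` is one research article: title, abstract, body (paragraphs
separated by blank lines), publication year, an origin tag and an optional
curation label (``positive`` = contains an evolutionary timetree).  A
:class:`Corpus` is an ordered, duplicate-free collection of documents.

Text normalization and tokenization are defined once here and shared by every
downstream stage (keyword filtering, phrase discovery, excerpt selection,
vectorization) so that character offsets and token boundaries agree across the
whole pipeline.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "LABELS",
    "Document",
    "Corpus",
    "normalize_text",
    "tokenize",
    "ngrams",
    "read_corpus",
    "write_corpus",
]

#: Allowed curation labels.
LABELS = ("positive", "negative")

_JSONL_FIELDS = ("id", "title", "abstract", "body", "year", "source", "label")

_WS_RUN_RE = re.compile(r"[ \t\f\v ]+")
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize_text(raw: str) -> str:
    """Normalize article text for matching and featurization.

    Lowercases, folds ligatures/diacritics to ASCII via NFKD (combining marks
    dropped, unmappable characters kept), folds CRLF/CR to LF, and collapses
    runs of horizontal whitespace to a single space.  Newlines are preserved
    verbatim — paragraph structure (blank lines) is load-bearing for caption
    detection.  Idempotent; performs no token splitting.
    """
    if not raw:
        return ""
    text = raw.replace("\r\n", "\n").replace("\r", "\n")
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = text.lower()
    return _WS_RUN_RE.sub(" ", text)


def tokenize(text: str, *, normalized: bool = False) -> list[str]:
    """Split text into word tokens.

    A token is a maximal run of ``[a-z0-9]`` on the normalized text, so
    hyphenated words split into their parts.  Pass ``normalized=True`` when
    the input already went through :func:`normalize_text`.
    """
    if not normalized:
        text = normalize_text(text)
    return _TOKEN_RE.findall(text)


def ngrams(tokens: Sequence[str], n_min: int = 1, n_max: int = 2) -> list[str]:
    """Contiguous n-grams (space-joined) of orders ``n_min..n_max``."""
    out: list[str] = []
    for n in range(n_min, n_max + 1):
        if n == 1:
            out.extend(tokens)
        else:
            out.extend(
                " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
            )
    return out


@dataclass
class Document:
    """One article with metadata and an optional curation label."""

    id: str
    body: str = ""
    title: str = ""
    abstract: str = ""
    year: int | None = None
    source: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("document id must be non-empty")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r} for document {self.id!r}; "
                f"expected one of {LABELS}"
            )
        if self.year is not None:
            self.year = int(self.year)

    def text(self, order: Sequence[str] = ("title", "abstract", "body")) -> str:
        """Concatenate the requested parts (default title+abstract+body)."""
        parts = [getattr(self, part) for part in order]
        return "\n\n".join(p for p in parts if p)

    def to_record(self) -> dict:
        return {f: getattr(self, f) for f in _JSONL_FIELDS}

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        if "id" not in rec or "body" not in rec:
            missing = {"id", "body"} - rec.keys()
            raise ValueError(f"record missing required field(s) {sorted(missing)}")
        label = rec.get("label")
        if label == "":
            label = None
        return cls(
            id=str(rec["id"]),
            body=rec.get("body") or "",
            title=rec.get("title") or "",
            abstract=rec.get("abstract") or "",
            year=rec.get("year"),
            source=rec.get("source") or "",
            label=label,
        )

    def with_(self, **changes) -> "Document":
        return replace(self, **changes)


@dataclass
class Corpus:
    """Ordered collection of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.id in seen:
                raise ValueError(f"duplicate document id {doc.id!r} in corpus")
            seen.add(doc.id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def ids(self) -> list[str]:
        return [d.id for d in self.documents]

    def get(self, doc_id: str) -> Document:
        for doc in self.documents:
            if doc.id == doc_id:
                return doc
        raise KeyError(doc_id)

    def labels(self) -> list[str | None]:
        return [d.label for d in self.documents]

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "Corpus":
        wanted = set(ids)
        docs = [d for d in self.documents if d.id in wanted]
        return Corpus(docs, provenance or self.provenance)

    def map_documents(self, fn, provenance: str | None = None) -> "Corpus":
        return Corpus([fn(d) for d in self.documents], provenance or self.provenance)


def _read_labels_csv(path: Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: labels CSV must have header 'id,label'")
        for row in reader:
            lab = (row["label"] or "").strip()
            if lab and lab not in LABELS:
                raise ValueError(
                    f"{path}: unknown label {lab!r} for id {row['id']!r}"
                )
            if lab:
                labels[row["id"]] = lab
    return labels


def read_corpus(
    path: str | Path,
    fmt: str = "jsonl",
    labels_csv: str | Path | None = None,
    provenance: str | None = None,
) -> Corpus:
    """Read a corpus from disk.

    ``fmt='jsonl'``: one JSON document per line with at least ``id`` and
    ``body``.  ``fmt='text_dir'``: a directory of ``<id>.txt`` files (body
    only), with an optional sidecar labels CSV (``id,label``; defaults to
    ``labels.csv`` inside the directory when present).

    Raises on duplicate ids (naming the id), malformed records (naming the
    line number) and unknown label strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    docs: list[Document] = []
    if fmt == "jsonl":
        labels = _read_labels_csv(Path(labels_csv)) if labels_csv else {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
                try:
                    doc = Document.from_record(rec)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                if doc.label is None and doc.id in labels:
                    doc = doc.with_(label=labels[doc.id])
                docs.append(doc)
    elif fmt == "text_dir":
        if not path.is_dir():
            raise NotADirectoryError(str(path))
        if labels_csv is None and (path / "labels.csv").exists():
            labels_csv = path / "labels.csv"
        labels = _read_labels_csv(Path(labels_csv)) if labels_csv else {}
        for txt in sorted(path.glob("*.txt")):
            body = txt.read_text(encoding="utf-8")
            docs.append(
                Document(id=txt.stem, body=body, label=labels.get(txt.stem))
            )
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    return Corpus(docs, provenance or str(path))


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSONL (one document per line, stable field order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc.to_record(), ensure_ascii=False, sort_keys=False))
            fh.write("\n")
    return path
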