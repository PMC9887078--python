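"""End-to-end triage pipeline: filter -> excerpt -> represent -> train -> evaluate.

A :class:`PipelineConfig` captures every knob (paths, excerpt window,
representation method, classifier family/grid, one seed) and round-trips
losslessly through YAML.  :func:`run_pipeline` executes the stages in order,
writing every artifact into a run directory together with a manifest that
records the config hash, seed, tool version and a content hash for each
output file — two runs with the same config and seed produce byte-identical
predictions and manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import __version__
from .classify import ClassifierSpec, grid_search_cv, predict_articles
from .corpus import Corpus, read_corpus, write_corpus
from .embeddings import train_doc_embeddings
from .evaluation import confusion_and_metrics, precision_per_year
from .excerpts import excerpt_corpus
from .filtering import FilterList, apply_filter
from .phrases import discover_phrases
from .representation import (
    DocMatrix,
    HashingEmbeddingProvider,
    TfidfTextVectorizer,
    embed_corpus,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline settings; one seed drives every stochastic step."""

    corpus: str
    out_dir: str = "run"
    labels_csv: str | None = None
    filter_phrases: str | None = None  # path; None disables the filter stage
    window: int | None = 800           # None = whole text
    representation: str = "tfidf"      # tfidf | hash | doc_embeddings
    classifier: str = "l1_logreg"
    grid: dict | None = None
    min_df: int = 2
    dims: int = 64
    cv_folds: int = 5
    test_fraction: float = 0.25
    threshold: float = 0.5
    discover: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def content_hash(self) -> str:
        """Hash of the computation-defining fields (output location and
        logging verbosity excluded)."""
        fields = {k: v for k, v in asdict(self).items()
                  if k not in ("out_dir", "log_level")}
        blob = json.dumps(fields, sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _split(corpus: Corpus, test_fraction: float, seed: int) -> tuple[Corpus, Corpus]:
    """Deterministic stratified train/test split by document label."""
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for label in ("positive", "negative"):
        ids = [d.id for d in corpus if d.label == label]
        perm = rng.permutation(len(ids))
        n_test = max(1, int(round(len(ids) * test_fraction)))
        chosen = {ids[i] for i in perm[:n_test]}
        test_ids.extend(i for i in ids if i in chosen)
        train_ids.extend(i for i in ids if i not in chosen)
    return corpus.subset(train_ids), corpus.subset(test_ids)


def _featurize(train: Corpus, test: Corpus, cfg: PipelineConfig) -> tuple[DocMatrix, DocMatrix]:
    if cfg.representation == "tfidf":
        vec = TfidfTextVectorizer(ngram_range=(1, 2), min_df=cfg.min_df)
        vec.fit([d.text() for d in train])
        cols = list(vec.vocabulary_)
        return (
            DocMatrix(train.ids(), cols, vec.transform([d.text() for d in train])),
            DocMatrix(test.ids(), cols, vec.transform([d.text() for d in test])),
        )
    if cfg.representation == "hash":
        provider = HashingEmbeddingProvider(dims=cfg.dims)
    elif cfg.representation == "doc_embeddings":
        provider = train_doc_embeddings(train, dims=cfg.dims, seed=cfg.seed)
    else:
        raise ValueError(f"unknown representation {cfg.representation!r}")
    return embed_corpus(train, provider), embed_corpus(test, provider)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    corpus = stage("load")(lambda: read_corpus(cfg.corpus, labels_csv=cfg.labels_csv))

    if cfg.filter_phrases:
        def _filter():
            flt = FilterList.from_file(cfg.filter_phrases)
            kept, report = apply_filter(corpus, flt)
            artifacts.append(write_corpus(kept, out / "filtered.jsonl"))
            artifacts.append(_write_json(report, out / "filter_report.json"))
            return kept
        corpus = stage("filter")(_filter)

    work = corpus
    if cfg.window is not None:
        def _excerpt():
            exc, report = excerpt_corpus(corpus, cfg.window)
            artifacts.append(write_corpus(exc, out / "excerpts.jsonl"))
            artifacts.append(_write_json(report, out / "excerpt_report.json"))
            return exc
        work = stage("excerpt")(_excerpt)

    labeled = Corpus([d for d in work if d.label is not None], work.provenance)
    if len(set(labeled.labels())) < 2:
        raise StageError("split", ValueError("need both labels to train"))

    if cfg.discover:
        def _discover():
            pl = discover_phrases(labeled, min_df=cfg.min_df, seed=cfg.seed)
            artifacts.append(_write_json(pl.to_dict(), out / "phrases.json"))
        stage("discover-phrases")(_discover)

    train, test = stage("split")(lambda: _split(labeled, cfg.test_fraction, cfg.seed))
    X_train, X_test = stage("featurize")(lambda: _featurize(train, test, cfg))

    def _train():
        spec = ClassifierSpec(cfg.classifier, cfg.grid, cfg.cv_folds, cfg.seed, cfg.threshold)
        model = grid_search_cv(X_train, train.labels(), spec)
        joblib.dump(model, out / "model.joblib")
        artifacts.append(out / "model.joblib")
        artifacts.append(_write_json(
            {"family": spec.family, "chosen_params": model.chosen_params,
             "cv_f1_mean": model.cv_f1_mean, "cv_f1_sd": model.cv_f1_sd},
            out / "model.json"))
        return model
    model = stage("train")(_train)

    def _predict():
        preds = predict_articles(model, X_test)
        path = out / "predictions.csv"
        preds.to_csv(path, index=False)
        artifacts.append(path)
        return preds
    preds = stage("predict")(_predict)

    def _evaluate():
        truth = [test.get(i).label for i in preds["id"]]
        report = confusion_and_metrics(truth, list(preds["predicted_label"]))
        years = [test.get(i).year for i in preds["id"]]
        per_year, year_info = precision_per_year(truth, list(preds["predicted_label"]), years)
        artifacts.append(_write_json({**report.to_dict(), **year_info}, out / "eval.json"))
        py_path = out / "per_year.csv"
        per_year.to_csv(py_path, index=False)
        artifacts.append(py_path)
        return report
    stage("evaluate")(_evaluate)

    manifest = {
        "tool": "timetriage",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "files": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
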