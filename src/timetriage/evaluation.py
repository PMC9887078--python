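"""Evaluation: confusion counts, precision/recall/F1, rates and per-year precision.

F1 is the selection and reporting metric throughout the pipeline because it
is maximized only when both error types are small: flagging irrelevant
articles (type I, wasting curator time) and missing timetree-containing
articles (type II, losing knowledge).  Zero-denominator metrics are defined
as 0 and flagged, so reports are reproducible on degenerate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

__all__ = ["EvalReport", "confusion_and_metrics", "rate", "precision_per_year"]


@dataclass
class EvalReport:
    """Confusion counts and derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    zero_division_flags: list[str] = field(default_factory=list)
    per_year: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "zero_division_flags": list(self.zero_division_flags),
        }


def confusion_and_metrics(truth: Sequence[str], predicted: Sequence[str]) -> EvalReport:
    """Exact confusion counts plus precision, recall and F1.

    Metrics with a zero denominator are reported as 0 with a flag naming the
    metric.
    """
    if len(truth) != len(predicted):
        raise ValueError(
            f"label sequences differ in length: {len(truth)} vs {len(predicted)}"
        )
    tn, fp, fn, tp = confusion_matrix(
        list(truth), list(predicted), labels=["negative", "positive"]
    ).ravel()
    flags: list[str] = []
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, flags = 0.0, flags + ["precision"]
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, flags = 0.0, flags + ["recall"]
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, flags = 0.0, flags + ["f1"]
    return EvalReport(int(tp), int(fp), int(tn), int(fn), precision, recall, f1, flags)


def rate(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage 100*numerator/denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def precision_per_year(
    truth: Sequence[str],
    predicted: Sequence[str],
    years: Sequence[int | None],
) -> tuple[pd.DataFrame, dict]:
    """Within-year precision for every year with >= 1 predicted positive.

    Documents without a year are excluded and counted in the returned report.
    The predicted-positive-weighted mean of yearly precisions reconstructs
    the overall precision over documents that carry a year.
    """
    if not (len(truth) == len(predicted) == len(years)):
        raise ValueError("truth, predicted and years must be aligned")
    df = pd.DataFrame({"truth": list(truth), "predicted": list(predicted),
                       "year": list(years)})
    n_missing = int(df["year"].isna().sum())
    df = df.dropna(subset=["year"])
    df["year"] = df["year"].astype(int)
    rows = []
    for year, grp in df.groupby("year"):
        n_pred = int((grp["predicted"] == "positive").sum())
        if n_pred == 0:
            continue
        n_tp = int(((grp["predicted"] == "positive") & (grp["truth"] == "positive")).sum())
        rows.append({"year": year, "n_predicted_positive": n_pred,
                     "n_true_positive": n_tp, "precision": n_tp / n_pred})
    table = pd.DataFrame(rows, columns=["year", "n_predicted_positive",
                                        "n_true_positive", "precision"])
    return table, {"n_missing_year": n_missing, "n_with_year": int(len(df))}
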